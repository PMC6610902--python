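"""Subpopulation decompositions of response ensembles.

Two decompositions are supported, mirroring the analysis of removing or
partitioning response data:

* terminal-threshold filtering — keep only cells whose GFAP reaches the
  differentiation threshold (0.8) at the *end* of the time interval
  ("final differentiated" subpopulation);
* per-signal k-means clustering of full-resolution trajectories into three
  clusters, rank-labelled C1 > C2 > C3 by descending mean GFAP, with
  capacities computed per rank label across all signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array

from .capacity import CapacityEstimate, estimate_capacity
from .sampling import ResponseDataset, SamplingPlan

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "TrajectoryKMeans",
    "filter_terminal_differentiated",
    "cluster_trajectories",
    "per_cluster_capacity",
]

CLUSTER_LABELS = ("C1", "C2", "C3")


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels for one signal's trajectory ensemble."""

    signal: object
    labels: np.ndarray                # (n_cells,) values in {0, 1, 2} = C1..C3
    centroids: np.ndarray             # (3, T)
    mean_gfap_per_cluster: np.ndarray  # (3,), descending
    degenerate: bool = False

    def label_names(self) -> np.ndarray:
        return np.array(CLUSTER_LABELS)[self.labels]


class TrajectoryKMeans(ClusterMixin, BaseEstimator):
    """k-means over full saved trajectories with rank-ordered labels.

    Cells are points in R^T (the saved time grid); clusters are relabelled
    in order of descending mean GFAP so that label 0 is always C1 (highest
    mean level), making labels comparable across signals.

    Parameters
    ----------
    n_clusters : int, default=3
    n_init : int, default=20
        Number of greedy (k-means++) seeded restarts; best inertia kept.
    random_state : int, default=0

    Attributes
    ----------
    labels_ : ndarray of rank-ordered cluster ids (0 = C1).
    cluster_centers_ : ndarray (n_clusters, T), ordered C1..C3.
    mean_gfap_ : ndarray (n_clusters,), descending.
    degenerate_ : bool
        True when fewer distinct clusters than requested could be formed.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 20,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters cells")
        n_distinct = np.unique(X, axis=0).shape[0]
        self.degenerate_ = n_distinct < self.n_clusters
        k_eff = min(self.n_clusters, n_distinct)
        km = KMeans(n_clusters=k_eff, n_init=self.n_init, init="k-means++",
                    random_state=self.random_state)
        raw = km.fit_predict(X)
        # rank clusters by descending mean GFAP over all cells x timepoints
        means = np.array([X[raw == j].mean() for j in range(k_eff)])
        order = np.argsort(-means, kind="stable")
        rank_of = np.empty(k_eff, dtype=int)
        rank_of[order] = np.arange(k_eff)
        self.labels_ = rank_of[raw]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.mean_gfap_ = means[order]
        self.inertia_ = km.inertia_
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def filter_terminal_differentiated(ens, threshold: float = 0.8):
    """Retain cells with terminal GFAP >= threshold.

    Returns ``(filtered_ensemble_or_None, n_kept)``; ``None`` with a logged
    flag when no cell passes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = ens.gfap[:, -1] >= threshold
    n_kept = int(keep.sum())
    if n_kept == 0:
        logger.warning("signal %s: no cell reaches GFAP %.2f at t_end",
                       getattr(ens, "signal", "?"), threshold)
        return None, 0
    full = getattr(ens, "full_state", None)
    return replace(ens, gfap=ens.gfap[keep],
                   full_state=None if full is None else full[keep]), n_kept


def cluster_trajectories(ens, n_clusters: int = 3, seed: int = 0,
                         n_init: int = 20) -> ClusterAssignment:
    """Cluster one signal's full-resolution trajectories into C1/C2/C3."""
    km = TrajectoryKMeans(n_clusters=n_clusters, n_init=n_init,
                          random_state=seed).fit(ens.gfap)
    if km.degenerate_:
        logger.warning("signal %s: degenerate clustering (fewer than %d "
                       "distinct trajectories)", getattr(ens, "signal", "?"),
                       n_clusters)
    return ClusterAssignment(
        signal=getattr(ens, "signal", None),
        labels=km.labels_,
        centroids=km.cluster_centers_,
        mean_gfap_per_cluster=km.mean_gfap_,
        degenerate=km.degenerate_,
    )


def per_cluster_capacity(
    ensembles: Sequence,
    assignments: Sequence[ClusterAssignment],
    plan: SamplingPlan,
    k: int = 5,
    n_clusters: int = 3,
    tol: float = 1e-4,
) -> list:
    """Capacity of each rank-matched cluster (C1..C3) across all signals.

    For each cluster label, the cells carrying that label in every signal are
    assembled (rank labels provide the cross-signal correspondence) into one
    ResponseDataset and the capacity estimated.  Signals contributing fewer
    than ``k + 1`` cells to a label are dropped from that label's dataset
    with a logged warning.
    """
    if len(ensembles) != len(assignments):
        raise ValueError("one assignment per ensemble required")
    idx = np.asarray(plan.chosen_indices)
    results = []
    for c in range(n_clusters):
        X_blocks, labels, counts = [], [], []
        s_used = 0
        for s, (ens, asg) in enumerate(zip(ensembles, assignments)):
            cells = np.flatnonzero(asg.labels == c)
            if len(cells) < k + 1:
                logger.warning("cluster %s: signal %s dropped (%d cells < k+1)",
                               CLUSTER_LABELS[c], s, len(cells))
                continue
            X_blocks.append(np.asarray(ens.gfap)[cells][:, idx])
            labels.append(np.full(len(cells), s_used))
            counts.append(len(cells))
            s_used += 1
        if s_used < 2:
            logger.warning("cluster %s: fewer than two usable signals; "
                           "capacity undefined", CLUSTER_LABELS[c])
            results.append(None)
            continue
        ds = ResponseDataset(vectors=np.vstack(X_blocks),
                             labels=np.concatenate(labels),
                             per_signal_counts=np.array(counts), plan=plan)
        est = estimate_capacity(ds, k=k, tol=tol)
        est.diagnostics["cluster"] = CLUSTER_LABELS[c]
        est.diagnostics["n_signals_used"] = s_used
        results.append(est)
    return results
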