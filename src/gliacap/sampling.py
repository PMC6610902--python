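"""Construction of d-dimensional response vectors from trajectory ensembles.

Each cell's GFAP time course is reduced to a ``d``-vector by reading it at
``d`` chosen time-grid indices.  Three strategies are provided:

symmetric
    ``d`` indices evenly spaced and symmetric about the midpoint of the time
    grid, spanning the interval interior (the default used throughout).
balanced
    the maximum-variance index inside each of ``d`` equal contiguous blocks
    of the grid (variance pooled across all cells of all signals).
greedy
    the ``d`` indices with the largest pooled variance overall.

Ties are always broken toward the earlier time point, so plans are
deterministic functions of the variance profile.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingPlan",
    "ResponseDataset",
    "TimepointSampler",
    "symmetric_plan",
    "pooled_timepoint_variance",
    "balanced_plan",
    "greedy_plan",
    "assemble_response_dataset",
]

STRATEGIES = ("symmetric", "balanced", "greedy")


@dataclass(frozen=True)
class SamplingPlan:
    """A choice of ``d`` strictly increasing time-grid indices."""

    strategy: str
    d: int
    chosen_indices: tuple

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        idx = tuple(int(i) for i in self.chosen_indices)
        if len(idx) != self.d or self.d < 1:
            raise ValueError("plan must have exactly d indices, d >= 1")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be unique and strictly increasing")
        if idx[0] < 0:
            raise ValueError("indices must be non-negative")
        object.__setattr__(self, "chosen_indices", idx)

    def to_json(self, grid: Optional[np.ndarray] = None) -> str:
        payload = {"strategy": self.strategy, "d": self.d,
                   "indices": list(self.chosen_indices)}
        if grid is not None:
            payload["grid_hash"] = hashlib.sha256(
                np.ascontiguousarray(grid, dtype=float).tobytes()
            ).hexdigest()[:16]
        return json.dumps(payload)


@dataclass
class ResponseDataset:
    """Per-cell response vectors with signal labels (the estimator's input)."""

    vectors: np.ndarray                 # (N, d)
    labels: np.ndarray                  # (N,) signal index, 0-based
    per_signal_counts: np.ndarray       # (S,)
    plan: Optional[SamplingPlan] = None
    signal_names: Optional[list] = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim == 1:
            self.vectors = self.vectors[:, None]
        self.labels = np.asarray(self.labels, dtype=int)
        self.per_signal_counts = np.asarray(self.per_signal_counts, dtype=int)
        if self.vectors.shape[0] != self.labels.shape[0]:
            raise ValueError("vectors and labels length mismatch")
        if self.per_signal_counts.sum() != self.vectors.shape[0]:
            raise ValueError("per_signal_counts must sum to the sample count")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("response vectors contain non-finite entries")

    @property
    def n_signals(self) -> int:
        return len(self.per_signal_counts)

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def symmetric_plan(time_grid, d: int, mode: str = "interior") -> SamplingPlan:
    """Evenly spaced indices symmetric about the midpoint of the grid.

    ``mode="interior"`` (default) places the ``j``-th index at
    ``round(j * (T-1) / (d+1))``, i.e. uniformly *around the middle* without
    touching the endpoints; ``mode="span"`` spreads the indices across the
    full grid including both endpoints.
    """
    T = len(time_grid) if np.ndim(time_grid) else int(time_grid)
    if d > T:
        raise ValueError(f"d={d} exceeds grid length T={T}")
    if d == T:
        idx = np.arange(T)
    elif mode == "span":
        idx = np.unique(np.round(np.linspace(0, T - 1, d)).astype(int))
        if len(idx) != d:
            raise ValueError("grid too short for a span plan of this d")
    elif mode == "interior":
        last = T - 1
        half = [int(round(j * last / (d + 1))) for j in range(1, d // 2 + 1)]
        mid = [last // 2] if d % 2 == 1 else []
        idx = np.array(half + mid + [last - i for i in reversed(half)])
        if len(np.unique(idx)) != d:
            raise ValueError("grid too short for an interior plan of this d")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SamplingPlan("symmetric", d, tuple(int(i) for i in idx))


def pooled_timepoint_variance(ensembles: Iterable) -> np.ndarray:
    """Per-time-point GFAP variance across all cells of all signals pooled."""
    ensembles = list(ensembles)
    grids = [np.asarray(e.time_grid) for e in ensembles]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("ensembles must share a common time grid")
    pooled = np.vstack([np.asarray(e.gfap) for e in ensembles])
    return pooled.var(axis=0)


def _blocks(T: int, d: int):
    """Split range(T) into d contiguous blocks; remainder on leading blocks."""
    base, rem = divmod(T, d)
    sizes = [base + 1 if j < rem else base for j in range(d)]
    start = 0
    for size in sizes:
        yield start, start + size
        start += size


def balanced_plan(variance: np.ndarray, d: int) -> SamplingPlan:
    """Argmax-variance index inside each of ``d`` equal contiguous blocks."""
    v = np.asarray(variance, dtype=float)
    T = len(v)
    if T < d:
        raise ValueError(f"d={d} exceeds grid length T={T}")
    idx = [lo + int(np.argmax(v[lo:hi])) for lo, hi in _blocks(T, d)]
    return SamplingPlan("balanced", d, tuple(idx))


def greedy_plan(variance: np.ndarray, d: int) -> SamplingPlan:
    """The ``d`` largest-variance indices overall, sorted by time."""
    v = np.asarray(variance, dtype=float)
    if len(v) < d:
        raise ValueError(f"d={d} exceeds grid length T={len(v)}")
    top = np.argsort(-v, kind="stable")[:d]  # stable sort: earlier index wins ties
    return SamplingPlan("greedy", d, tuple(sorted(int(i) for i in top)))


def assemble_response_dataset(
    ensembles: Sequence,
    plan: SamplingPlan,
    transform: str = "raw",
    eps_init: float = 1e-8,
) -> ResponseDataset:
    """Stack per-cell response vectors for all signals into one dataset.

    Each row is one cell's GFAP value at the plan's indices.  With
    ``transform="fold"`` every trajectory is first divided by its own initial
    value; cells with initial GFAP <= ``eps_init`` are excluded and counted.
    """
    if transform not in ("raw", "fold"):
        raise ValueError(f"unknown transform {transform!r}")
    blocks, labels, counts, names = [], [], [], []
    idx = np.asarray(plan.chosen_indices)
    for s, ens in enumerate(ensembles):
        gfap = np.asarray(ens.gfap, dtype=float)
        if idx.max() >= gfap.shape[1]:
            raise ValueError("plan indices exceed the ensemble time grid")
        if transform == "fold":
            init = gfap[:, 0]
            keep = init > eps_init
            n_drop = int((~keep).sum())
            if n_drop:
                logger.warning(
                    "fold transform: excluded %d cell(s) of signal %s with "
                    "initial GFAP <= %g", n_drop, s, eps_init)
            gfap = gfap[keep] / gfap[keep, 0:1]
        vec = gfap[:, idx]
        blocks.append(vec)
        labels.append(np.full(vec.shape[0], s))
        counts.append(vec.shape[0])
        names.append(getattr(ens, "signal", s))
    return ResponseDataset(
        vectors=np.vstack(blocks),
        labels=np.concatenate(labels),
        per_signal_counts=np.array(counts),
        plan=plan,
        signal_names=names,
    )


class TimepointSampler(TransformerMixin, BaseEstimator):
    """scikit-learn transformer selecting ``d`` trajectory time points.

    ``fit(X)`` takes full trajectories (n_cells_total, T), computes the
    pooled per-time-point variance, and freezes the sampling plan;
    ``transform(X)`` returns the (n, d) response vectors.

    Parameters
    ----------
    strategy : {"symmetric", "balanced", "greedy"}, default="symmetric"
    d : int, default=6

    Attributes
    ----------
    plan_ : SamplingPlan
    variance_ : ndarray of shape (T,)
    """

    def __init__(self, strategy: str = "symmetric", d: int = 6):
        self.strategy = strategy
        self.d = d

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.variance_ = X.var(axis=0)
        T = X.shape[1]
        if self.strategy == "symmetric":
            self.plan_ = symmetric_plan(T, self.d)
        elif self.strategy == "balanced":
            self.plan_ = balanced_plan(self.variance_, self.d)
        elif self.strategy == "greedy":
            self.plan_ = greedy_plan(self.variance_, self.d)
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.n_features_in_ = T
        return self

    def transform(self, X):
        check_is_fitted(self, "plan_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("trajectory length differs from fit")
        return X[:, np.asarray(self.plan_.chosen_indices)]
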