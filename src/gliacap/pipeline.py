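"""Replicated end-to-end experiments: simulate, sample, estimate, compare.

One *condition* is a (model, representation, strategy/subpopulation)
combination; each replicate re-simulates all 16 ensembles with a derived
seed and re-runs the full estimation, so replicate spread covers both
simulation and estimation noise.  Results land in a tidy DataFrame with one
row per (condition, replicate).

Seed derivation is counter-based: ``SeedSequence(master_seed,
spawn_key=(replicate, model_index, signal_index))`` so every stream is
reproducible from the master seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .capacity import estimate_capacity
from .descriptors import DESCRIPTOR_NAMES, descriptor_table
from .models import (SimulationConfig, build_signal_grid, load_model_spec,
                     simulate_ensemble)
from .sampling import (ResponseDataset, assemble_response_dataset,
                       balanced_plan, greedy_plan, pooled_timepoint_variance,
                       symmetric_plan)
from .subpop import (cluster_trajectories, filter_terminal_differentiated,
                     per_cluster_capacity)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ComparisonResult",
    "derive_seed",
    "simulate_model_ensembles",
    "descriptor_dataset",
    "run_replicates",
    "compare_conditions",
    "render_outputs",
]

MODEL_NAMES = ("AN", "CLE", "CLE_MINUS")


@dataclass
class ExperimentConfig:
    """What to run and at which scale."""

    models: Sequence[str] = ("AN", "CLE", "CLE_MINUS")
    descriptors: bool = True
    strategies: Sequence[str] = ("symmetric",)
    transforms: Sequence[str] = ("raw",)
    subpopulations: bool = False
    n_replicates: int = 10
    k: int = 5
    d: int = 6
    n_cells: int = 500
    dt: float = 0.01
    save_stride: int = 10
    t_end: float = 48.0
    master_seed: int = 0
    differentiation_threshold: float = 0.8

    def __post_init__(self) -> None:
        for m in self.models:
            if m.upper().replace("-", "_MINUS") not in MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(n_cells=self.n_cells, t_end=self.t_end,
                                dt=self.dt, save_stride=self.save_stride,
                                seed=seed)


@dataclass
class ComparisonResult:
    """Welch t-test between two conditions' replicate capacities."""

    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    degenerate: bool = False


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and a key path."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_model_ensembles(model: str, config: ExperimentConfig,
                             replicate: int = 0):
    """Simulate the 16-signal grid for one model variant and replicate."""
    model_idx = MODEL_NAMES.index(model.upper().replace("-", "_MINUS"))
    spec = load_model_spec(model)
    ensembles = []
    for s_idx, signal in enumerate(build_signal_grid(model)):
        seed = derive_seed(config.master_seed, replicate, model_idx, s_idx)
        ensembles.append(simulate_ensemble(spec, signal, config.sim_config(seed)))
    return ensembles


def descriptor_dataset(ensembles, name: str) -> ResponseDataset:
    """Scalar-descriptor responses as a d=1 ResponseDataset."""
    vals, labels, counts = [], [], []
    for s, ens in enumerate(ensembles):
        tb = descriptor_table(ens, name)
        vals.append(tb.values)
        labels.append(np.full(len(tb.values), s))
        counts.append(len(tb.values))
    return ResponseDataset(vectors=np.concatenate(vals)[:, None],
                           labels=np.concatenate(labels),
                           per_signal_counts=np.array(counts))


def _condition_rows(model, ensembles, config: ExperimentConfig, replicate):
    """Capacity rows for every representation of one simulated model."""
    rows = []
    T = len(ensembles[0].time_grid)

    def add(representation, strategy, subpop, est, n_cells):
        rows.append({
            "model": model, "representation": representation,
            "strategy": strategy, "subpopulation": subpop,
            "replicate": replicate, "capacity_bits": est.capacity_bits,
            "mi_uniform_bits": est.mi_at_uniform,
            "converged": est.converged, "n_cells_per_signal": n_cells,
        })

    if config.descriptors:
        for name in DESCRIPTOR_NAMES:
            ds = descriptor_dataset(ensembles, name)
            add(name, "static", "full", estimate_capacity(ds, k=config.k),
                int(ds.per_signal_counts.min()))

    variance = pooled_timepoint_variance(ensembles)
    plans = {}
    for strategy in config.strategies:
        if strategy == "symmetric":
            plans[strategy] = symmetric_plan(T, config.d)
        elif strategy == "balanced":
            plans[strategy] = balanced_plan(variance, config.d)
        elif strategy == "greedy":
            plans[strategy] = greedy_plan(variance, config.d)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    for transform in config.transforms:
        for strategy, plan in plans.items():
            ds = assemble_response_dataset(ensembles, plan, transform=transform)
            add(f"vector_{transform}", strategy, "full",
                estimate_capacity(ds, k=config.k),
                int(ds.per_signal_counts.min()))

    if config.subpopulations:
        plan = plans.get("symmetric") or symmetric_plan(T, config.d)
        # final differentiated subpopulation (terminal threshold filter)
        filt, labels, counts = [], [], []
        s_used = 0
        for s, ens in enumerate(ensembles):
            kept, n_kept = filter_terminal_differentiated(
                ens, config.differentiation_threshold)
            if kept is None or n_kept < config.k + 1:
                logger.warning("final-differentiated: signal %d dropped "
                               "(%d cells)", s, n_kept)
                continue
            filt.append(kept.gfap[:, np.asarray(plan.chosen_indices)])
            labels.append(np.full(n_kept, s_used))
            counts.append(n_kept)
            s_used += 1
        if s_used >= 2:
            ds = ResponseDataset(vectors=np.vstack(filt),
                                 labels=np.concatenate(labels),
                                 per_signal_counts=np.array(counts), plan=plan)
            add("vector_raw", "symmetric", "final_differentiated",
                estimate_capacity(ds, k=config.k),
                int(ds.per_signal_counts.min()))
        # k-means trajectory clusters C1..C3
        assignments = [
            cluster_trajectories(ens, seed=derive_seed(
                config.master_seed, replicate, 900 + s))
            for s, ens in enumerate(ensembles)
        ]
        for c, est in enumerate(per_cluster_capacity(
                ensembles, assignments, plan, k=config.k)):
            if est is not None:
                add("vector_raw", "symmetric", f"C{c + 1}", est,
                    est.diagnostics.get("n_signals_used", 0))
    return rows


def run_replicates(config: ExperimentConfig) -> pd.DataFrame:
    """Full replicated experiment; tidy DataFrame, one row per estimate."""
    rows = []
    for replicate in range(config.n_replicates):
        for model in config.models:
            try:
                ensembles = simulate_model_ensembles(model, config, replicate)
                rows.extend(_condition_rows(model, ensembles, config, replicate))
            except Exception:
                logger.exception("replicate %d model %s failed; skipping",
                                 replicate, model)
    table = pd.DataFrame(rows)
    if not table.empty:
        expected = table.groupby(
            ["model", "representation", "strategy", "subpopulation"]
        )["replicate"].count()
        if expected.nunique() > 1:
            logger.warning("partial table: unequal replicate counts per condition")
    return table


def _select(table: pd.DataFrame, cond: dict) -> np.ndarray:
    mask = np.ones(len(table), dtype=bool)
    for key, val in cond.items():
        mask &= (table[key] == val).to_numpy()
    return table.loc[mask, "capacity_bits"].to_numpy()


def compare_conditions(table: pd.DataFrame, condition_a: dict,
                       condition_b: dict) -> ComparisonResult:
    """Welch (unequal-variance) two-sample t-test on replicate capacities."""
    a = _select(table, condition_a)
    b = _select(table, condition_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per condition")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate:
        t_stat, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
        logger.warning("degenerate zero-variance comparison flagged")
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        condition_a=str(condition_a), condition_b=str(condition_b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
        t_statistic=float(t_stat), p_value=float(p), degenerate=degenerate)


def render_outputs(outdir, table: Optional[pd.DataFrame] = None,
                   ensembles: Optional[Sequence] = None,
                   descriptor_names: Sequence[str] = DESCRIPTOR_NAMES):
    """Summary figures: trajectory fans, descriptor heatmaps, capacity bars.

    Writes PNGs into ``outdir``; any missing input is skipped with a warning.
    Returns the list of written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if ensembles is not None:
        doses = sorted({e.signal.ct_dose for e in ensembles})
        noises = list(dict.fromkeys(e.signal.noise_label for e in ensembles))
        fig, axes = plt.subplots(len(noises), len(doses),
                                 figsize=(3 * len(doses), 2.2 * len(noises)),
                                 sharex=True, sharey=True, squeeze=False)
        for ens in ensembles:
            i = noises.index(ens.signal.noise_label)
            j = doses.index(ens.signal.ct_dose)
            ax = axes[i][j]
            t, g = ens.time_grid, ens.gfap
            mean, sd = g.mean(0), g.std(0)
            half = 1.96 * sd / np.sqrt(g.shape[0])
            ax.plot(t, mean, color="darkblue", lw=1.5)
            ax.fill_between(t, mean - half, mean + half, alpha=0.3,
                            color="steelblue")
            if i == 0:
                ax.set_title(f"{ens.signal.ct_dose} ng/ml")
            if j == 0:
                ax.set_ylabel(ens.signal.noise_label)
        fig.supxlabel("time (h)")
        fig.supylabel("GFAP")
        path = outdir / "trajectory_fans.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

        for name in descriptor_names:
            grid = np.full((len(noises), len(doses)), np.nan)
            for ens in ensembles:
                tb = descriptor_table(ens, name)
                grid[noises.index(ens.signal.noise_label),
                     doses.index(ens.signal.ct_dose)] = tb.values.mean()
            fig, ax = plt.subplots(figsize=(4, 3.2))
            im = ax.imshow(grid, cmap="viridis")
            ax.set_xticks(range(len(doses)), [str(d) for d in doses])
            ax.set_yticks(range(len(noises)), noises)
            ax.set_xlabel("CT dose (ng/ml)")
            ax.set_title(f"mean {name}")
            fig.colorbar(im)
            path = outdir / f"heatmap_{name}.png"
            fig.savefig(path, dpi=110, bbox_inches="tight")
            plt.close(fig)
            written.append(path)

    if table is not None and not table.empty:
        summary = (table.groupby(["model", "representation", "strategy",
                                  "subpopulation"])["capacity_bits"]
                   .agg(["mean", "std", "count"]).reset_index())
        summary.to_csv(outdir / "capacity_summary.csv", index=False)
        written.append(outdir / "capacity_summary.csv")
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(summary)), 4))
        labels = [" / ".join(map(str, r)) for r in
                  summary[["model", "representation", "strategy",
                           "subpopulation"]].itertuples(index=False)]
        ax.bar(range(len(summary)), summary["mean"],
               yerr=summary["std"].fillna(0.0), capsize=3)
        ax.set_xticks(range(len(summary)), labels, rotation=60, ha="right",
                      fontsize=7)
        ax.set_ylabel("channel capacity (bits)")
        fig.tight_layout()
        path = outdir / "capacity_bars.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    return [str(p) for p in written]
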