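"""Scalar summary descriptors of single-cell GFAP trajectories.

Three descriptors reduce each cell's time course to one number:

* ``max_response`` — the maximum GFAP level over the saved time points,
* ``max_fold_change`` — the maximum divided by the initial GFAP level,
* ``auc`` — the trapezoidal area under the curve over the full interval.

The fold transformation divides each cell's whole trajectory by its own
initial value, so every transformed trajectory starts at 1.  Cells whose
initial GFAP is at or below ``EPS_INIT`` are excluded from fold-based
quantities (and counted), never assigned infinities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorTable",
    "EPS_INIT",
    "DESCRIPTOR_NAMES",
    "max_response",
    "max_fold_change",
    "auc",
    "fold_transform",
    "descriptor_table",
]

#: Minimum admissible initial GFAP (dimensionless) for fold operations.
EPS_INIT = 1e-8

DESCRIPTOR_NAMES = ("max_response", "max_fold_change", "auc")


@dataclass
class DescriptorTable:
    """One scalar per cell for a single descriptor and signal."""

    descriptor_name: str
    values: np.ndarray
    signal: object = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.descriptor_name not in DESCRIPTOR_NAMES:
            raise ValueError(f"unknown descriptor {self.descriptor_name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values contain non-finite entries")


def _as_matrix(gfap) -> np.ndarray:
    a = np.asarray(gfap, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] == 0:
        raise ValueError("empty trajectory")
    if not np.all(np.isfinite(a)):
        raise ValueError("trajectory contains non-finite values")
    return a


def max_response(gfap) -> np.ndarray | float:
    """Maximum GFAP level over the saved time points (per cell)."""
    a = _as_matrix(gfap)
    out = a.max(axis=1)
    return float(out[0]) if np.ndim(gfap) == 1 else out


def max_fold_change(gfap, eps_init: float = EPS_INIT):
    """Maximum GFAP divided by initial GFAP, per cell.

    Returns ``(values, admissible)`` for 2-D input, where ``admissible`` marks
    cells with initial value > ``eps_init``; inadmissible cells carry NaN and
    are logged.  For a single 1-D trajectory a float is returned (raises if
    inadmissible).
    """
    a = _as_matrix(gfap)
    init = a[:, 0]
    ok = init > eps_init
    vals = np.full(a.shape[0], np.nan)
    vals[ok] = a[ok].max(axis=1) / init[ok]
    if np.ndim(gfap) == 1:
        if not ok[0]:
            raise ValueError(f"initial GFAP {init[0]} <= eps_init={eps_init}")
        return float(vals[0])
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("max_fold_change: excluded %d cell(s) with initial "
                       "GFAP <= %g", n_bad, eps_init)
    return vals, ok


def auc(gfap, time_grid) -> np.ndarray | float:
    """Trapezoidal area under the trajectory over the time grid (value·hours)."""
    a = _as_matrix(gfap)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) != a.shape[1]:
        raise ValueError("time grid length must match trajectory length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    out = np.trapezoid(a, t, axis=1)
    return float(out[0]) if np.ndim(gfap) == 1 else out


def fold_transform(ens, eps_init: float = EPS_INIT):
    """Divide each cell's trajectory by its own initial value.

    Accepts a TrajectoryEnsemble (returns a new one with inadmissible cells
    dropped) or a bare matrix (returns ``(matrix, admissible_mask)``).
    """
    gfap = np.asarray(getattr(ens, "gfap", ens), dtype=float)
    init = gfap[:, 0]
    ok = init > eps_init
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("fold_transform: excluded %d cell(s) with initial "
                       "GFAP <= %g", n_bad, eps_init)
    folded = gfap[ok] / gfap[ok, 0:1]
    if hasattr(ens, "gfap"):
        full = getattr(ens, "full_state", None)
        return replace(ens, gfap=folded,
                       full_state=None if full is None else full[ok])
    return folded, ok


def descriptor_table(ens, name: str,
                     time_grid: Optional[np.ndarray] = None) -> DescriptorTable:
    """Compute one descriptor for every cell of an ensemble."""
    gfap = np.asarray(getattr(ens, "gfap", ens), dtype=float)
    grid = np.asarray(getattr(ens, "time_grid", time_grid), dtype=float)
    signal = getattr(ens, "signal", None)
    if name == "max_response":
        return DescriptorTable(name, max_response(gfap), signal)
    if name == "max_fold_change":
        vals, ok = max_fold_change(gfap)
        return DescriptorTable(name, vals[ok], signal, n_excluded=int((~ok).sum()))
    if name == "auc":
        return DescriptorTable(name, auc(gfap, grid), signal)
    raise ValueError(f"unknown descriptor {name!r}")
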