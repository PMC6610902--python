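"""Stochastic models of CT-induced glioma differentiation.

Three Itô SDE variants of the same 10-state signaling network are simulated
with Euler-Maruyama integration:

AN
    additive noise: each state receives a constant-intensity Brownian term
    whose standard deviation is a fixed percentage (0.1/1/5/10%) of the
    state's dynamic scale (all concentrations are normalized to scale 1).
CLE
    chemical-Langevin-style noise: intrinsic noise enters each state as a
    white-noise term proportional to the square root of that state's total
    reaction propensity (production + degradation), scaled by ``sigma_int``;
    extrinsic noise is a per-cell, trajectory-constant log-normal
    perturbation of the kinetic parameters with log-std ``sigma_ext``.
CLE-
    the CLE model with the ultrasensitive cyclin D1 positive-feedback term
    scaled down by ``feedback_scale`` (0 = feedback removed).

The network follows the published wiring: cholera toxin (CT) activates the
PKA/CREB, PI3K/AKT/pGSK3beta and IL6/JAK2/STAT3 branches; CREB drives cyclin
D1 translocation/degradation, collapsing the bistable cyclin D1 switch;
loss of cyclin D1 de-represses GFAP, the differentiation marker.  A cell is
called differentiated when its GFAP level reaches 0.8.

The channel input ("signal") is one of 16 combinations of 4 CT doses
(0, 5, 7.5, 10 ng/ml) and 4 noise settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "CT_DOSES",
    "AN_NOISE_LABELS",
    "CLE_NOISE_LABELS",
    "ModelSpec",
    "Signal",
    "SimulationConfig",
    "TrajectoryEnsemble",
    "load_model_spec",
    "build_signal_grid",
    "simulate_ensemble",
    "make_cle_minus",
    "differentiation_potential",
    "drift_field",
]

STATE_NAMES = ("PKA", "CREB", "PI3K", "AKT", "pGSK3B",
               "IL6", "JAK2", "STAT3", "CCND1", "GFAP")
N_STATES = 10
N_DRIFT_PARAMS = 41

CT_DOSES = (0.0, 5.0, 7.5, 10.0)  # ng/ml

#: AN noise labels and the corresponding additive intensities (fraction of
#: the unit dynamic scale of the normalized concentrations).
AN_NOISE_LABELS = {"0.1%": 0.001, "1%": 0.01, "5%": 0.05, "10%": 0.1}

#: CLE noise labels -> (sigma_int, sigma_ext), the standard deviations of
#: intrinsic and extrinsic noise.
CLE_NOISE_LABELS = {
    "LL": (0.001, 0.001),
    "HL": (0.1, 0.001),
    "LH": (0.001, 0.1),
    "HH": (0.1, 0.1),
}

#: AN noise enters the nine signaling states; the GFAP readout integrates
#: upstream fluctuations rather than receiving its own Brownian term.
_AN_NOISE_MASK = np.array([1.0] * 9 + [0.0])

#: Hill exponents are structural and are not perturbed by extrinsic noise.
_UNPERTURBED = ("n_ct_pka", "n_ct_pi3k", "n_ct_il6",
                "n_ccnd1_fb", "n_ccnd1_gfap")

VARIANTS = ("AN", "CLE", "CLE_MINUS")


@dataclass
class ModelSpec:
    """One SDE model variant: wiring constants plus noise configuration."""

    variant: str
    state_names: tuple = STATE_NAMES
    drift_params: dict = field(default_factory=dict)
    noise_params: dict = field(default_factory=dict)
    feedback_scale: float = 1.0
    initial_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if tuple(self.state_names) != STATE_NAMES or len(self.state_names) != N_STATES:
            raise ValueError(f"model must have exactly the {N_STATES} network states")
        if len(self.drift_params) != N_DRIFT_PARAMS:
            raise ValueError(
                f"model must have exactly {N_DRIFT_PARAMS} drift parameters, "
                f"got {len(self.drift_params)}")
        if not 1 <= len(self.noise_params) <= 2:
            raise ValueError("model must have 1-2 noise parameters")
        if self.variant in ("AN", "CLE"):
            if self.feedback_scale != 1.0:
                raise ValueError("feedback_scale must be 1 for AN/CLE")
        elif not 0.0 <= self.feedback_scale < 1.0:
            raise ValueError("CLE_MINUS requires 0 <= feedback_scale < 1")

    @property
    def x0(self) -> np.ndarray:
        return np.array([self.initial_state[s] for s in self.state_names])


@dataclass(frozen=True)
class Signal:
    """A composite channel input: (CT dose, noise setting)."""

    ct_dose: float                 # ng/ml
    noise_label: str
    sigma_int: Optional[float] = None   # CLE only
    sigma_ext: Optional[float] = None   # CLE only
    sigma_add: Optional[float] = None   # AN only

    def __post_init__(self) -> None:
        if self.ct_dose < 0:
            raise ValueError("CT dose must be non-negative")


@dataclass
class SimulationConfig:
    """Euler-Maruyama integration settings."""

    n_cells: int = 500
    t_end: float = 48.0       # hours
    dt: float = 0.01          # hours
    save_stride: int = 10     # keep every save_stride-th step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        n_steps = self.t_end / self.dt
        if abs(n_steps - round(n_steps)) > 1e-8:
            raise ValueError("t_end must be an integral number of steps")
        if round(n_steps) % self.save_stride != 0:
            raise ValueError("save_stride must divide the step count")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class TrajectoryEnsemble:
    """GFAP time courses for one cell population under one signal."""

    signal: Signal
    time_grid: np.ndarray            # hours, (T,)
    gfap: np.ndarray                 # (n_cells, T)
    full_state: Optional[np.ndarray] = None   # (n_cells, 10, T)
    seed_used: Optional[int] = None

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.gfap = np.asarray(self.gfap, dtype=float)
        if self.gfap.shape[1] != len(self.time_grid):
            raise ValueError("gfap and time_grid length mismatch")
        if np.any(np.diff(self.time_grid) <= 0) or self.time_grid[0] != 0:
            raise ValueError("time grid must start at 0 and increase strictly")
        if not np.all(np.isfinite(self.gfap)) or np.any(self.gfap < 0):
            raise ValueError("GFAP values must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.gfap.shape[0]


def load_model_spec(variant: str = "CLE",
                    feedback_scale: Optional[float] = None) -> ModelSpec:
    """Load a model variant from the packaged (synthetic) parameter file."""
    variant = variant.upper()
    variant = "CLE_MINUS" if variant in ("CLE-", "CLE_MINUS") else variant
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    text = resources.files("gliacap.data").joinpath(
        "parameters_synthetic.yaml").read_text()
    raw = yaml.safe_load(text)
    noise_key = "AN" if variant == "AN" else "CLE"
    spec = ModelSpec(
        variant="CLE" if variant == "CLE_MINUS" else variant,
        drift_params=dict(raw["drift_params"]),
        noise_params=dict(raw["noise_params"][noise_key]),
        initial_state=dict(raw["states"]),
    )
    if variant == "CLE_MINUS":
        spec = make_cle_minus(spec, 0.0 if feedback_scale is None else feedback_scale)
    return spec


def make_cle_minus(spec: ModelSpec, feedback_scale: float = 0.0) -> ModelSpec:
    """Derive the CLE- variant by scaling down the cyclin D1 feedback term."""
    if spec.variant != "CLE":
        raise ValueError("CLE- must be derived from a CLE spec")
    if not 0.0 <= feedback_scale < 1.0:
        raise ValueError("feedback_scale must lie in [0, 1)")
    return replace(spec, variant="CLE_MINUS", feedback_scale=feedback_scale)


def build_signal_grid(variant: str) -> list:
    """The 16-signal grid (4 CT doses x 4 noise settings), dose-major order."""
    variant = variant.upper()
    variant = "CLE_MINUS" if variant in ("CLE-", "CLE_MINUS") else variant
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    signals = []
    for dose in CT_DOSES:
        if variant == "AN":
            for label, sigma in AN_NOISE_LABELS.items():
                signals.append(Signal(dose, label, sigma_add=sigma))
        else:
            for label, (s_int, s_ext) in CLE_NOISE_LABELS.items():
                signals.append(Signal(dose, label, sigma_int=s_int, sigma_ext=s_ext))
    return signals


# ---------------------------------------------------------------------------
# drift / propensities
# ---------------------------------------------------------------------------

def _hill(x, K, n):
    xn = np.power(np.maximum(x, 0.0), n)
    return xn / (np.power(K, n) + xn)


def _mm(x, K):
    return x / (K + x)


def _propensities(X, dose, p, feedback_scale):
    """Production and consumption propensities for every state.

    ``X`` is (n_cells, 10); parameter values in ``p`` may be scalars or
    per-cell arrays (extrinsic noise).  Returns ``(prod, deg)`` arrays of the
    same shape as ``X``; the drift is ``prod - deg``.
    """
    PKA, CREB, PI3K, AKT, GSK, IL6, JAK, STAT, C, G = (X[:, j] for j in range(10))
    prod = np.empty_like(X)
    deg = np.empty_like(X)

    prod[:, 0] = p["k_pka_act"] * _hill(dose, p["K_ct_pka"], p["n_ct_pka"]) * (1 - PKA)
    deg[:, 0] = p["k_pka_deact"] * PKA
    prod[:, 1] = p["k_creb_act"] * _mm(PKA, p["K_pka_creb"]) * (1 - CREB)
    deg[:, 1] = p["k_creb_deact"] * CREB

    prod[:, 2] = p["k_pi3k_act"] * _hill(dose, p["K_ct_pi3k"], p["n_ct_pi3k"]) * (1 - PI3K)
    deg[:, 2] = p["k_pi3k_deact"] * PI3K
    prod[:, 3] = p["k_akt_act"] * _mm(PI3K, p["K_pi3k_akt"]) * (1 - AKT)
    deg[:, 3] = p["k_akt_deact"] * AKT
    prod[:, 4] = p["k_gsk_act"] * _mm(AKT, p["K_akt_gsk"]) * (1 - GSK)
    deg[:, 4] = p["k_gsk_deact"] * GSK

    prod[:, 5] = p["k_il6_act"] * _hill(dose, p["K_ct_il6"], p["n_ct_il6"]) * (1 - IL6)
    deg[:, 5] = p["k_il6_deact"] * IL6
    prod[:, 6] = p["k_jak_act"] * _mm(IL6, p["K_il6_jak"]) * (1 - JAK)
    deg[:, 6] = p["k_jak_deact"] * JAK
    prod[:, 7] = p["k_stat_act"] * _mm(JAK, p["K_jak_stat"]) * (1 - STAT)
    deg[:, 7] = p["k_stat_deact"] * STAT

    prod[:, 8] = (p["k_ccnd1_basal"]
                  + feedback_scale * p["k_ccnd1_fb"]
                  * _hill(C, p["K_ccnd1_fb"], p["n_ccnd1_fb"]))
    deg[:, 8] = (p["k_ccnd1_deg"]
                 * (1 + p["k_ccnd1_deg_ct"] * _mm(CREB, p["K_creb_deg"]))
                 / (1 + p["k_ccnd1_stab"] * GSK) * C)

    # cyclin D1 represses GFAP production: K^m / (K^m + C^m)
    Km = np.power(p["K_ccnd1_gfap"], p["n_ccnd1_gfap"])
    Cm = np.power(np.maximum(C, 0.0), p["n_ccnd1_gfap"])
    inh = Km / (Km + Cm)
    prod[:, 9] = (p["k_gfap_basal"] + p["k_gfap_creb"] * CREB
                  + p["k_gfap_stat"] * STAT) * inh * (1 - G)
    deg[:, 9] = p["k_gfap_deg"] * G
    return prod, deg


def drift_field(X, dose, params, feedback_scale=1.0) -> np.ndarray:
    """Deterministic drift (prod - deg) of the network; used by ODE oracles."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    prod, deg = _propensities(X, dose, params, feedback_scale)
    return prod - deg


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _cell_generators(seed: int, n_cells: int):
    """Independent per-cell RNG streams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(n_cells + 1)
    return [np.random.Generator(np.random.Philox(c)) for c in children[:-1]], \
        np.random.Generator(np.random.Philox(children[-1]))


def _perturbed_params(params: dict, sigma_ext: float, rng_cells, skip=_UNPERTURBED):
    """Per-cell log-normal parameter multipliers (trajectory-constant)."""
    out = {}
    n = len(rng_cells)
    for name, value in params.items():
        if name in skip or sigma_ext == 0:
            out[name] = value
        else:
            z = np.array([g.standard_normal() for g in rng_cells])
            out[name] = value * np.exp(sigma_ext * z)
    return out


def simulate_ensemble(spec: ModelSpec, signal: Signal, config: SimulationConfig,
                      keep_full_state: bool = False) -> TrajectoryEnsemble:
    """Euler-Maruyama integration of one 500-cell (by default) ensemble.

    Each cell uses its own counter-based RNG stream derived from
    ``config.seed``, so ensembles are bit-reproducible and a cell's path does
    not depend on how many other cells are simulated.  States are clamped to
    zero after every step.
    """
    n, dt = config.n_cells, config.dt
    n_steps, stride = config.n_steps, config.save_stride
    rng_cells, rng_aux = _cell_generators(config.seed, n)

    params = dict(spec.drift_params)
    if spec.variant == "AN":
        sigma_add = signal.sigma_add
        if sigma_add is None:
            sigma_add = AN_NOISE_LABELS.get(signal.noise_label,
                                            spec.noise_params.get("sigma_add", 0.0))
        sigma_int = None
    else:
        sigma_int = signal.sigma_int
        sigma_ext = signal.sigma_ext
        if sigma_int is None:
            sigma_int = spec.noise_params.get("sigma_int", 0.0)
        if sigma_ext is None:
            sigma_ext = spec.noise_params.get("sigma_ext", 0.0)
        if sigma_ext:
            params = _perturbed_params(params, sigma_ext, rng_cells)
        sigma_add = None

    X = np.tile(spec.x0, (n, 1))
    # Cell-to-cell variability of the starting state, log-normal (abundances
    # are positive).  CLE: extrinsic noise is cell-to-cell variability, so the
    # initial spread equals sigma_ext.  AN: the pre-stimulus population sits at
    # the stationary spread of its own fluctuations, ~ sigma/sqrt(2*r) with
    # relaxation r ~ 2/h, i.e. about half the noise intensity.
    z0 = np.stack([g.standard_normal(N_STATES) for g in rng_cells])
    scale0 = 0.5 * sigma_add if spec.variant == "AN" else sigma_ext
    if scale0:
        X = X * np.exp(scale0 * z0)
    T = n_steps // stride + 1
    saved = np.empty((n, N_STATES, T)) if keep_full_state else None
    gfap = np.empty((n, T))
    gfap[:, 0] = X[:, -1]
    if keep_full_state:
        saved[:, :, 0] = X

    sqrt_dt = np.sqrt(dt)
    dose = signal.ct_dose
    chunk = 400  # steps of pre-drawn noise per cell
    step = 0
    save_i = 1
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = np.stack([g.standard_normal((m, N_STATES)) for g in rng_cells])
        for j in range(m):
            prod, deg = _propensities(X, dose, params, spec.feedback_scale)
            drift = prod - deg
            if spec.variant == "AN":
                g_noise = sigma_add * _AN_NOISE_MASK
            else:
                g_noise = sigma_int * np.sqrt(prod + deg)
            X = X + drift * dt + g_noise * sqrt_dt * noise[:, j, :]
            np.maximum(X, 0.0, out=X)
            step += 1
            if step % stride == 0:
                if not np.all(np.isfinite(X)):
                    bad = np.argwhere(~np.isfinite(X))[0]
                    raise RuntimeError(
                        f"numerical blow-up: non-finite state "
                        f"{STATE_NAMES[bad[1]]} in cell {bad[0]} at "
                        f"t={step * dt:.2f} h")
                gfap[:, save_i] = X[:, -1]
                if keep_full_state:
                    saved[:, :, save_i] = X
                save_i += 1

    time_grid = np.arange(T) * dt * stride
    return TrajectoryEnsemble(signal=signal, time_grid=time_grid, gfap=gfap,
                              full_state=saved, seed_used=config.seed)


def differentiation_potential(ens: TrajectoryEnsemble, threshold: float = 0.8,
                              criterion: str = "any") -> float:
    """Fraction of cells whose GFAP reaches ``threshold``.

    ``criterion="any"`` counts a cell if its GFAP reaches the threshold at
    any saved time point (the differentiation-potential metric);
    ``criterion="terminal"`` requires GFAP(t_end) >= threshold (the
    subpopulation filter used for the "final differentiated" analysis).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ens.n_cells == 0:
        raise ValueError("empty ensemble")
    if criterion == "any":
        hits = (ens.gfap >= threshold).any(axis=1)
    elif criterion == "terminal":
        hits = ens.gfap[:, -1] >= threshold
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return float(hits.mean())
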