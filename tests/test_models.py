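"""Signal grid, model specs, and the Euler-Maruyama SDE simulator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gliacap.models import (AN_NOISE_LABELS, CLE_NOISE_LABELS, CT_DOSES,
                            ModelSpec, Signal, SimulationConfig,
                            build_signal_grid, differentiation_potential,
                            drift_field, load_model_spec, make_cle_minus,
                            simulate_ensemble)


def small_cfg(seed=0, n_cells=4, dt=0.02):
    return SimulationConfig(n_cells=n_cells, t_end=48.0, dt=dt,
                            save_stride=int(round(0.2 / dt)), seed=seed)


# ---------------------------------------------------------------- signal grid

def test_signal_grid_cle_matches_noise_table():
    grid = build_signal_grid("CLE")
    assert len(grid) == 16
    assert len(set(grid)) == 16
    # dose-major ordering
    assert [s.ct_dose for s in grid] == sorted(s.ct_dose for s in grid)
    hh10 = [s for s in grid if s.ct_dose == 10.0 and s.noise_label == "HH"]
    assert hh10[0].sigma_int == 0.1 and hh10[0].sigma_ext == 0.1
    ll = [s for s in grid if s.noise_label == "LL"]
    assert all(s.sigma_int == 0.001 and s.sigma_ext == 0.001 for s in ll)


def test_signal_grid_an_labels():
    grid = build_signal_grid("AN")
    assert len(grid) == 16
    assert {s.noise_label for s in grid} == {"0.1%", "1%", "5%", "10%"}
    assert {s.ct_dose for s in grid} == set(CT_DOSES)
    assert AN_NOISE_LABELS["10%"] == 0.1


# ----------------------------------------------------------------- model spec

def test_spec_has_ten_states_and_41_parameters():
    for variant in ("AN", "CLE"):
        spec = load_model_spec(variant)
        assert len(spec.state_names) == 10
        assert len(spec.drift_params) == 41
        assert 1 <= len(spec.noise_params) <= 2
        assert spec.feedback_scale == 1.0


def test_spec_validation_errors():
    spec = load_model_spec("CLE")
    with pytest.raises(ValueError):
        ModelSpec(variant="CLE", drift_params={"a": 1.0},
                  noise_params=spec.noise_params,
                  initial_state=spec.initial_state)
    with pytest.raises(ValueError):
        make_cle_minus(spec, 1.0)
    with pytest.raises(ValueError):
        make_cle_minus(spec, -0.1)
    with pytest.raises(ValueError):
        make_cle_minus(load_model_spec("AN"), 0.5)


def test_cle_minus_differs_only_in_cyclin_feedback():
    """The CLE- drift differs from CLE exactly by the scaled cyclin D1
    positive-feedback term, in the cyclin D1 component only."""
    cle = load_model_spec("CLE")
    minus = make_cle_minus(cle, 0.1)
    assert minus.variant == "CLE_MINUS" and minus.feedback_scale == 0.1
    rng = np.random.default_rng(0)
    X = rng.uniform(0.0, 1.0, size=(5, 10))
    d_full = drift_field(X, 7.5, cle.drift_params, 1.0)
    d_weak = drift_field(X, 7.5, cle.drift_params, 0.1)
    diff = d_full - d_weak
    assert np.all(diff[:, :8] == 0) and np.all(diff[:, 9] == 0)
    p = cle.drift_params
    C = X[:, 8]
    fb = (p["k_ccnd1_fb"] * C ** p["n_ccnd1_fb"]
          / (p["K_ccnd1_fb"] ** p["n_ccnd1_fb"] + C ** p["n_ccnd1_fb"]))
    assert diff[:, 8] == pytest.approx(0.9 * fb)


# ----------------------------------------------------------------- simulation

def test_zero_noise_cle_cells_identical():
    spec = load_model_spec("CLE")
    sig = Signal(10.0, "LL", sigma_int=0.0, sigma_ext=0.0)
    ens = simulate_ensemble(spec, sig, small_cfg())
    assert np.all(ens.gfap == ens.gfap[0])


def test_zero_noise_an_matches_ode_oracle():
    """With zero noise the EM path must agree with an adaptive ODE solve of
    the same drift field to 1e-3 relative sup-norm."""
    spec = load_model_spec("AN")
    sig = Signal(10.0, "0.1%", sigma_add=0.0)
    cfg = SimulationConfig(n_cells=2, t_end=48.0, dt=0.005, save_stride=200,
                           seed=1)
    ens = simulate_ensemble(spec, sig, cfg, keep_full_state=True)

    def rhs(t, x):
        return drift_field(x[None, :], 10.0, spec.drift_params, 1.0)[0]

    sol = solve_ivp(rhs, (0, 48.0), spec.x0, t_eval=ens.time_grid,
                    rtol=1e-8, atol=1e-10)
    scale = np.abs(sol.y).max()
    err = np.abs(ens.full_state[0] - sol.y).max() / scale
    assert err < 1e-3


def test_seeded_simulation_bit_reproducible(cle_spec):
    sig = Signal(5.0, "HH", sigma_int=0.1, sigma_ext=0.1)
    a = simulate_ensemble(cle_spec, sig, small_cfg(seed=9))
    b = simulate_ensemble(cle_spec, sig, small_cfg(seed=9))
    c = simulate_ensemble(cle_spec, sig, small_cfg(seed=10))
    assert np.array_equal(a.gfap, b.gfap)
    assert not np.array_equal(a.gfap, c.gfap)


def test_cell_paths_do_not_depend_on_population_size(cle_spec):
    """Per-cell RNG streams: the first cells' paths are unchanged when more
    cells are simulated."""
    sig = Signal(5.0, "HH", sigma_int=0.1, sigma_ext=0.1)
    small = simulate_ensemble(cle_spec, sig, small_cfg(seed=4, n_cells=3))
    large = simulate_ensemble(cle_spec, sig, small_cfg(seed=4, n_cells=6))
    assert np.array_equal(small.gfap, large.gfap[:3])


def test_states_stay_non_negative_under_strong_noise():
    spec = load_model_spec("AN")
    sig = Signal(0.0, "10%", sigma_add=0.1)
    ens = simulate_ensemble(spec, sig, small_cfg(seed=2, n_cells=20),
                            keep_full_state=True)
    assert np.all(ens.full_state >= 0)
    assert np.all(np.isfinite(ens.full_state))


def test_blowup_aborts_with_diagnostic():
    spec = load_model_spec("CLE")
    spec.drift_params["k_ccnd1_fb"] = 1e308
    sig = Signal(10.0, "LL", sigma_int=0.0, sigma_ext=0.0)
    with pytest.raises(RuntimeError, match="cell"):
        simulate_ensemble(spec, sig, small_cfg())


def test_grid_refinement_halving_dt_changes_mean_by_under_2pct(cle_spec):
    """Weak-convergence sanity: halving the step changes the population-mean
    GFAP course by < 2% sup-norm at the low-noise setting."""
    sig = Signal(10.0, "LL", sigma_int=0.001, sigma_ext=0.001)
    coarse = simulate_ensemble(cle_spec, sig, SimulationConfig(
        n_cells=30, dt=0.04, save_stride=10, seed=6))
    fine = simulate_ensemble(cle_spec, sig, SimulationConfig(
        n_cells=30, dt=0.02, save_stride=20, seed=6))
    diff = np.abs(coarse.gfap.mean(0) - fine.gfap.mean(0)).max()
    assert diff < 0.02 * max(1.0, np.abs(fine.gfap).max())


def test_dose_monotone_terminal_gfap_at_low_noise(cle_spec):
    means = []
    for dose in CT_DOSES:
        sig = Signal(dose, "LL", sigma_int=0.001, sigma_ext=0.001)
        ens = simulate_ensemble(cle_spec, sig, small_cfg(seed=3, n_cells=10))
        means.append(ens.gfap[:, -1].mean())
    assert all(b >= a - 1e-6 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]


# ------------------------------------------------- differentiation potential

def test_differentiation_potential_examples():
    class E:
        def __init__(self, gfap):
            self.gfap = np.asarray(gfap, dtype=float)
            self.n_cells = self.gfap.shape[0]

    assert differentiation_potential(E(np.zeros((5, 4)))) == 0.0
    assert differentiation_potential(E(np.ones((5, 4)))) == 1.0
    g = np.array([[0.9, 0.1], [0.85, 0.85], [0.81, 0.5], [0.2, 0.3],
                  [0.1, 0.79]])
    assert differentiation_potential(E(g)) == pytest.approx(0.6)
    assert differentiation_potential(E(g), criterion="terminal") == \
        pytest.approx(0.2)
    with pytest.raises(ValueError):
        differentiation_potential(E(g), threshold=0.0)
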