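"""kNN likelihoods, plug-in mutual information, and capacity maximization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliacap.capacity import (ChannelCapacityEstimator, estimate_capacity,
                              knn_likelihoods, maximize_capacity,
                              mutual_information, unit_ball_volume)
from gliacap.fixtures import make_separated_clusters


def grid_search_capacity(L, step=0.01):
    """Brute-force simplex search over 3 signal weights (oracle)."""
    assert L.n_signals == 3
    best = -np.inf
    for a in np.arange(0.0, 1.0 + 1e-12, step):
        for b in np.arange(0.0, 1.0 - a + 1e-12, step):
            w = np.array([a, b, 1.0 - a - b])
            w = np.clip(w, 0.0, None)
            w = w / w.sum()
            best = max(best, mutual_information(L, w))
    return best


def two_class_1d_data():
    x0 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    x1 = x0 + 100.0
    X = np.concatenate([x0, x1])[:, None]
    y = np.repeat([0, 1], 5)
    return X, y


def test_knn_likelihood_hand_example():
    """d=1, class {0..4}, k=1: leave-one-out density at the member x=0 is
    k/(m c_1 r) = 1/(4 * 2 * 1) = 0.125."""
    X, y = two_class_1d_data()
    L = knn_likelihoods(X, k=1, y=y)
    assert L.L[0, 0] == pytest.approx(1.0 / (4 * 2 * 1.0))
    # non-member evaluation: distance from 100 to nearest of class 0 is 96,
    # m = 5 -> 1/(5*2*96)
    assert L.L[0, 5] == pytest.approx(1.0 / (5 * 2 * 96.0))
    # widely separated classes: own-class likelihood dominates cross-class
    own = L.L[L.labels, np.arange(10)]
    cross = L.L[1 - L.labels, np.arange(10)]
    assert np.all(own > 100 * cross)


def test_unit_ball_volumes():
    assert unit_ball_volume(1) == pytest.approx(2.0)
    assert unit_ball_volume(2) == pytest.approx(np.pi)
    assert unit_ball_volume(3) == pytest.approx(4.0 * np.pi / 3.0)


def test_duplicate_points_get_distance_floor():
    X = np.zeros((12, 2))
    y = np.repeat([0, 1], 6)
    L = knn_likelihoods(X, k=2, y=y)
    assert np.all(np.isfinite(L.L)) and np.all(L.L > 0)


def test_small_class_raises_with_class_name():
    X = np.arange(8.0)[:, None]
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
    with pytest.raises(ValueError, match="1"):
        knn_likelihoods(X, k=3, y=y)


def test_mi_zero_for_indistinguishable_signals():
    """Identical likelihood rows mean the response says nothing about the
    signal: the plug-in MI is exactly 0."""
    row = np.linspace(0.2, 2.0, 10)
    L = knn_likelihoods(np.r_[row, row][:, None], k=2,
                        y=np.repeat([0, 1], 10))
    L.L[1] = L.L[0]
    assert mutual_information(L, np.array([0.5, 0.5])) == pytest.approx(0.0, abs=1e-12)


def test_mi_approaches_one_bit_for_separated_supports():
    """Two well-separated classes at uniform weights: own-class likelihoods
    dominate and the plug-in MI approaches its 1-bit ceiling from below."""
    X, y = two_class_1d_data()
    L = knn_likelihoods(X, k=2, y=y)
    mi = mutual_information(L, np.array([0.5, 0.5]))
    assert mi == pytest.approx(1.0, abs=0.05)
    assert mi <= 1.0 + 1e-12


def test_mi_matches_bruteforce_double_sum():
    """The vectorized MI equals the literal double sum over signals/cells."""
    rng = np.random.default_rng(5)
    S, n_s = 3, 4
    Lmat = rng.uniform(0.1, 3.0, size=(S, S * n_s))
    labels = np.repeat(np.arange(S), n_s)
    from gliacap.capacity import LikelihoodMatrix
    L = LikelihoodMatrix(L=Lmat, labels=labels,
                         counts=np.full(S, n_s), k=1, d=1)
    w = np.array([0.2, 0.5, 0.3])
    expected = 0.0
    for s in range(S):
        inner = 0.0
        for i in np.flatnonzero(labels == s):
            mix = sum(w[t] * Lmat[t, i] for t in range(S))
            inner += np.log2(Lmat[s, i] / mix)
        expected += w[s] * inner / n_s
    assert mutual_information(L, w) == pytest.approx(max(expected, 0.0), abs=1e-12)


def test_off_simplex_weights_rejected():
    X, y = two_class_1d_data()
    L = knn_likelihoods(X, k=2, y=y)
    with pytest.raises(ValueError):
        mutual_information(L, np.array([0.7, 0.7]))


@pytest.mark.parametrize("seed", [7, 19])
def test_capacity_matches_simplex_grid_search(seed):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10),
                        rng.normal(4, 1, 10)])[:, None]
    y = np.repeat([0, 1, 2], 10)
    L = knn_likelihoods(X, k=3, y=y)
    oracle = grid_search_capacity(L)
    est = maximize_capacity(L)
    assert est.capacity_bits == pytest.approx(oracle, abs=1e-3)
    assert est.capacity_bits >= est.mi_at_uniform - 1e-9


def test_symmetric_two_signal_instance_gives_uniform_weights():
    X, y = two_class_1d_data()
    L = knn_likelihoods(X, k=2, y=y)
    est = maximize_capacity(L)
    assert est.weights_opt == pytest.approx([0.5, 0.5], abs=1e-6)


def test_duplicated_signal_capacity_equals_reduced_channel():
    """A signal whose conditional response law duplicates another's makes the
    objective flat along the shared-weight direction: the 3-signal capacity
    equals the 2-signal capacity, and the optimizer stays on the ridge."""
    from gliacap.capacity import LikelihoodMatrix
    rng = np.random.default_rng(3)
    n = 10
    L0 = rng.uniform(0.5, 2.0, 2 * n)
    L1 = rng.uniform(0.5, 2.0, 2 * n) * np.r_[np.full(n, 0.1), np.full(n, 4.0)]
    L2mat = np.vstack([L0, L1])
    lab2 = np.repeat([0, 1], n)
    # class 2 = exact copy of class 0: same likelihood law, duplicated samples
    L3mat = np.vstack([np.r_[L0, L0[:n]], np.r_[L1, L1[:n]],
                       np.r_[L0, L0[:n]]])
    lab3 = np.r_[lab2, np.full(n, 2)]
    two = maximize_capacity(LikelihoodMatrix(L2mat, lab2, [n, n], k=1, d=1))
    three = maximize_capacity(LikelihoodMatrix(L3mat, lab3, [n, n, n], k=1, d=1))
    assert three.capacity_bits == pytest.approx(two.capacity_bits, abs=1e-3)
    # weight mass on the duplicated pair matches the 2-signal optimum
    w = three.weights_opt
    assert w[0] + w[2] == pytest.approx(two.weights_opt[0], abs=5e-3)


def test_slsqp_route_agrees_with_fixed_point():
    rng = np.random.default_rng(11)
    X = rng.normal(0, 1, (40, 2)) + np.repeat([[0, 0], [2, 1]], 20, axis=0)
    y = np.repeat([0, 1], 20)
    L = knn_likelihoods(X, k=4, y=y)
    fp = maximize_capacity(L)
    gen = maximize_capacity(L, method="slsqp")
    assert fp.capacity_bits == pytest.approx(gen.capacity_bits, abs=2e-3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), S=st.integers(2, 5))
def test_capacity_bounds_and_monotone_iterates(seed, S):
    """0 <= capacity <= log2(S); the fixed-point objective never decreases."""
    rng = np.random.default_rng(seed)
    n_s = 8
    centers = rng.uniform(-2, 2, size=S)
    X = (centers[:, None] + rng.normal(0, 1.0, size=(S, n_s))).reshape(-1, 1)
    y = np.repeat(np.arange(S), n_s)
    L = knn_likelihoods(X, k=2, y=y)
    est = maximize_capacity(L)
    assert -1e-12 <= est.capacity_bits <= np.log2(S) + 1e-9
    assert est.capacity_bits >= est.mi_at_uniform - 1e-9
    trace = np.array(est.diagnostics["objective_trace"])
    assert np.all(np.diff(trace) >= -1e-12)


def test_sklearn_estimator_api():
    from sklearn.base import clone
    from sklearn.pipeline import Pipeline
    from gliacap.sampling import TimepointSampler

    ds, truth, _ = make_separated_clusters(S=4, n_per_signal=60, d=2,
                                           separation=40.0, sigma=1.0, seed=0)
    est = ChannelCapacityEstimator(k=5)
    assert clone(est).get_params()["k"] == 5
    est.fit(ds.vectors, ds.labels)
    assert est.capacity_ == pytest.approx(2.0, abs=0.02)
    assert est.weights_.shape == (4,)
    assert est.converged_
    assert est.score() == est.capacity_

    # composes with a sklearn pipeline: trajectories in, capacity out
    rng = np.random.default_rng(2)
    traj = np.tile(np.linspace(0, 1, 30), (120, 1))
    labels = np.repeat(np.arange(4), 30)
    traj[:, 10] += labels * 5.0 + 0.01 * rng.standard_normal(120)
    pipe = Pipeline([("sampler", TimepointSampler(strategy="greedy", d=1)),
                     ("capacity", ChannelCapacityEstimator(k=3))])
    pipe.fit(traj, labels)
    assert pipe.named_steps["capacity"].capacity_ > 1.9
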