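"""Measurement operations, batch-kernel equivalence, small harness runs."""

import numpy as np
import pytest

from ratecal import _batch
from ratecal.experiments import (
    ConvergenceTime,
    PRESETS,
    Scenario,
    _scenario_dynamics,
    _setup_scenario,
    _steady_init_cov,
    ci_coverage,
    decoding_rmse,
    empirical_convergence_time,
    empirical_error_covariance,
    normalized_rmse,
    run_day_shift,
    run_rate_sweep,
)
from ratecal.filters import AdaptationTrace, FilterState, kf_update, ppf_update


def make_trace(errors, truth=None, delta=1.0):
    errors = np.asarray(errors, dtype=float)
    truth = np.zeros(errors.shape[1]) if truth is None else np.asarray(truth)
    return AdaptationTrace(means=truth[None, :] - errors,
                           cov_diags=np.ones_like(errors),
                           observations=np.zeros(len(errors)),
                           truth=truth, delta=delta)


# ---------------------------------------------------------------------------
# measurement operations
# ---------------------------------------------------------------------------

def test_empirical_covariance_constant_error_is_zero():
    tr = make_trace(np.tile([0.5, -0.2], (100, 1)))
    np.testing.assert_allclose(empirical_error_covariance(tr, 0.5), 0.0, atol=1e-12)


def test_empirical_covariance_recovers_known_sigma(rng):
    Sigma = np.array([[2.0, 0.7], [0.7, 1.0]])
    errs = rng.multivariate_normal(np.zeros(2), Sigma, size=100_000)
    est = empirical_error_covariance(make_trace(errs), steady_window=1.0)
    np.testing.assert_allclose(est, Sigma, rtol=0.05, atol=0.02)


def test_empirical_covariance_window_too_short():
    tr = make_trace(np.zeros((20, 2)))
    with pytest.raises(ValueError):
        empirical_error_covariance(tr, steady_window=0.1)


def test_convergence_time_geometric_decay():
    e0 = np.array([1.0, 0.0])
    errs = np.stack([0.5**t * e0 for t in range(40)])
    out = empirical_convergence_time(make_trace(errs), e_rest=0.05, dwell=1)
    assert out == ConvergenceTime(seconds=5.0, converged=True)


def test_convergence_time_flat_never_crosses():
    errs = np.tile([1.0, 0.0], (50, 1))
    out = empirical_convergence_time(make_trace(errs), e_rest=0.05, dwell=1)
    assert not out.converged
    assert out.seconds == 50.0


def test_convergence_time_dwell_rejects_transient_dip():
    rel = np.ones(100)
    rel[20:25] = 0.01        # brief dip, should not count with dwell=10
    rel[60:] = 0.01          # sustained crossing
    errs = rel[:, None] * np.array([[1.0, 0.0]])
    out = empirical_convergence_time(make_trace(errs), e_rest=0.05, dwell=10)
    assert out.seconds == 60.0


def test_normalized_rmse_hand_values():
    assert normalized_rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert normalized_rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(
        np.sqrt(1 / 3) / 3)
    with pytest.raises(ValueError):
        normalized_rmse([1, 2], [5, 5])


def test_ci_coverage_gaussian_quantile(rng):
    cov = np.diag([2.0, 0.5])
    errs = rng.multivariate_normal(np.zeros(2), cov, size=50_000)
    frac = ci_coverage(make_trace(errs), cov, steady_window=1.0)
    assert frac == pytest.approx(0.9545, abs=0.006)


def test_ci_coverage_zero_width_bounds(rng):
    errs = rng.normal(size=(1000, 2))
    assert ci_coverage(make_trace(errs), np.zeros((2, 2)), 1.0) == 0.0


def test_decoding_rmse_points_on_line():
    target = np.array([0.3, 0.0])
    pos = np.column_stack([np.linspace(0, 0.3, 50), np.zeros(50)])
    assert decoding_rmse(pos, [(0, 50, target)]) == 0.0


def test_decoding_rmse_constant_offset():
    target = np.array([0.0, 0.3])
    pos = np.column_stack([0.1 * np.ones(50), np.linspace(0, 0.3, 50)])
    assert decoding_rmse(pos, [(0, 50, target)]) == pytest.approx(0.1)


def test_decoding_rmse_validates_segments():
    with pytest.raises(ValueError):
        decoding_rmse(np.zeros((10, 2)), [])
    with pytest.raises(ValueError):
        decoding_rmse(np.zeros((10, 2)), [(0, 20, np.array([0.3, 0.0]))])


# ---------------------------------------------------------------------------
# batch kernels reproduce the reference recursions
# ---------------------------------------------------------------------------

def test_kf_kernel_matches_reference_updates(rng):
    """The compiled multi-channel kernel equals step-by-step kf_update."""
    T, C = 40, 3
    V = np.column_stack([np.ones(T), 0.4 * rng.standard_normal((T, 2))])
    truth = rng.normal(size=(C, 3))
    init = rng.normal(size=(C, 3))
    Z = rng.uniform(5.0, 10.0, C)
    s = 1e-3
    S0 = np.repeat(0.5 * np.eye(3)[None], C, axis=0)
    g_sum = np.zeros((C, 3))
    gg_sum = np.zeros((C, 3, 3))
    err = np.zeros((T, C, 3), dtype=np.float32)
    bounds = np.ones((C, 3))
    _batch.kf_adapt_batch(V, truth, init, Z, s, S0, 77, 0, bounds,
                          False, 10, 1.0, g_sum, gg_sum, err, 1)
    # reference path with the same observation stream
    np.random.seed(77)
    ys = np.empty((T, C))
    for t in range(T):
        for c in range(C):
            ys[t, c] = truth[c] @ V[t] + np.sqrt(Z[c]) * np.random.normal()
    for c in range(C):
        st = FilterState(init[c], 0.5 * np.eye(3))
        for t in range(T):
            st = kf_update(st, s, ys[t, c], V[t], Z[c])
            np.testing.assert_allclose(truth[c] - st.mean, err[t, c],
                                       rtol=2e-5, atol=2e-6)


def test_ppf_kernel_matches_reference_updates(rng):
    T, C = 60, 2
    V = np.column_stack([np.ones(T), 0.5 * rng.standard_normal((T, 2))])
    truth = np.column_stack([np.log(rng.uniform(5, 20, C)),
                             rng.normal(scale=0.8, size=(C, 2))])
    init = truth + rng.normal(scale=0.3, size=(C, 3))
    delta, r = 0.001, 1e-4
    Q0 = np.repeat(1e-2 * np.eye(3)[None], C, axis=0)
    g_sum = np.zeros((C, 3))
    gg_sum = np.zeros((C, 3, 3))
    err = np.zeros((T, C, 3), dtype=np.float32)
    _batch.ppf_adapt_batch(V, truth, init, delta, r, Q0, 5, 0,
                           np.ones((C, 3)), g_sum, gg_sum, err, 1)
    np.random.seed(5)
    spikes = np.empty((T, C))
    for t in range(T):
        for c in range(C):
            p = min(np.exp(truth[c] @ V[t]) * delta, 1.0)
            spikes[t, c] = 1.0 if np.random.random() < p else 0.0
    for c in range(C):
        st = FilterState(init[c], 1e-2 * np.eye(3))
        for t in range(T):
            st = ppf_update(st, r, int(spikes[t, c]), V[t], delta)
            np.testing.assert_allclose(truth[c] - st.mean, err[t, c],
                                       rtol=2e-5, atol=2e-6)


def test_kf_kernel_concurrent_Z_matches_reference(rng):
    """Covariance-matching inside the kernel equals the reference estimator."""
    from ratecal.filters import NoiseEstimatorState, covariance_match_Z

    T = 300
    V = np.column_stack([np.ones(T), 0.4 * rng.standard_normal((T, 2))])
    truth = np.array([[2.0, 5.0, -3.0]])
    init = np.array([[0.0, 0.0, 0.0]])
    Z = np.array([50.0])
    s, Lwin, z_init = 1e-3, 20, 30.0
    S0 = np.repeat(np.eye(3)[None], 1, axis=0)
    g_sum = np.zeros((1, 3))
    gg_sum = np.zeros((1, 3, 3))
    err = np.zeros((T, 1, 3), dtype=np.float32)
    _, _, z_final, psi_final = _batch.kf_adapt_batch(
        V, truth, init, Z, s, S0, 13, 0, np.ones((1, 3)),
        True, Lwin, z_init, g_sum, gg_sum, err, 1)
    # reference path
    np.random.seed(13)
    ys = np.array([truth[0] @ V[t] + np.sqrt(Z[0]) * np.random.normal()
                   for t in range(T)])
    st = FilterState(init[0], np.eye(3))
    est = NoiseEstimatorState(window_length=Lwin, z_floor=1e-6 * z_init,
                              current_Z=z_init)
    for t in range(T):
        cov_pred = st.cov + s * np.eye(3)
        q = ys[t] - V[t] @ st.mean
        covariance_match_Z(est, q, V[t] @ cov_pred @ V[t])
        st = kf_update(st, s, ys[t], V[t], est.current_Z)
    np.testing.assert_allclose(psi_final[0], st.mean, rtol=1e-8)
    assert z_final[0] == pytest.approx(est.current_Z, rel=1e-8)


def test_closed_loop_kernel_reproducible():
    sc = PRESETS["kf_periodic"]
    setup = _setup_scenario(sc, 3, n_ref_trials=8)
    from ratecal.ofc import lqg_gain, peak_reach_speed

    L = lqg_gain(setup.dyn, sc.cost)
    targets = np.tile([0.3, 0.0], (40, 1))
    args = lambda: (targets, L, sc.delta, setup.dyn.alpha_decay,  # noqa: E731
                    float(np.sqrt(setup.dyn.W[2, 2])), 0.2,
                    2.0 * peak_reach_speed(sc.delta, sc.cost, sc.radius),
                    setup.truth, setup.Z, 1e-4, True,
                    setup.init.copy(),
                    np.repeat(np.eye(3)[None], sc.n_channels, axis=0),
                    setup.init.copy(), np.zeros(4), 1e-2 * np.eye(4),
                    np.zeros(2), 9)
    dec_a, int_a = _batch.kf_closed_loop(*args())
    dec_b, int_b = _batch.kf_closed_loop(*args())
    np.testing.assert_array_equal(dec_a, dec_b)
    np.testing.assert_array_equal(int_a, int_b)
    assert np.all(np.isfinite(dec_a))


# ---------------------------------------------------------------------------
# harness runs (small)
# ---------------------------------------------------------------------------

def test_sweep_empirical_covariance_monotone_and_stable():
    grid = [1e-5, 1e-4]
    a = run_rate_sweep("kf_periodic", rate_grid=grid, reps=2, seed=21)
    b = run_rate_sweep("kf_periodic", rate_grid=grid, reps=2, seed=22)
    # empirical covariance norm grows with the rate (Monte-Carlo side of the
    # monotonicity theorem) and is stable across disjoint seeds
    assert a.empirical_cov_norm[1] > a.empirical_cov_norm[0]
    np.testing.assert_allclose(a.empirical_cov_norm, b.empirical_cov_norm,
                               rtol=0.2)
    frame = a.to_frame()
    assert len(frame) == 2 and "empirical_cov_norm" in frame


def test_sweep_identical_seeds_identical_results():
    grid = [5e-5]
    a = run_rate_sweep("kf_periodic", rate_grid=grid, reps=2, seed=5)
    b = run_rate_sweep("kf_periodic", rate_grid=grid, reps=2, seed=5)
    assert a.empirical_cov_norm[0] == b.empirical_cov_norm[0]
    assert a.empirical_conv_time[0] == b.empirical_conv_time[0]


def test_day_shift_two_days_relearn():
    out = run_day_shift("kf_periodic", rate=2e-4, seed=4)
    d1, d2 = out["days"]
    assert d1["converged"] and d2["converged"]
    for d in (d1, d2):
        assert 0.90 <= d["coverage"] <= 0.99


def test_scenario_dynamics_overrides():
    sc = Scenario(kind="gaussian", velocity_tau=0.3, noise_std=0.05)
    dyn = _scenario_dynamics(sc)
    assert dyn.alpha_decay == pytest.approx(np.exp(-0.1 / 0.3))
    assert dyn.W[2, 2] == pytest.approx(0.05**2)


def test_steady_init_cov_matches_kappa_eigs():
    from ratecal.calibration import kappa

    setup = _setup_scenario(PRESETS["kf_periodic"], 1, n_ref_trials=8)
    S0 = _steady_init_cov(setup, 1e-4)
    info = setup.infos[0]
    eig = np.sort(np.linalg.eigvalsh(S0[0]))
    expect = np.sort([kappa(h, 1e-4) for h in info.eigvals])
    np.testing.assert_allclose(eig, expect, rtol=1e-10)
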