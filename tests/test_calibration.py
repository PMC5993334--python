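"""Calibration engine: forward maps, inverse maps, monotonicity, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratecal.calibration import (
    AverageInformation,
    LearningRateCalibrator,
    admissible_interval,
    average_information_gaussian,
    average_information_point_process,
    convergence_factor,
    error_decay_map,
    kappa,
    predict_convergence_time,
    rate_for_error_bound,
    rate_for_time_bound,
    steady_state_covariance,
    conservative_rate,
)


def info_from_eigs(eigvals, U=None):
    eigvals = np.asarray(eigvals, dtype=float)
    n = len(eigvals)
    U = np.eye(n) if U is None else U
    return AverageInformation.from_matrix((U * eigvals) @ U.T)


def random_orthogonal(n, rng):
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    return q


# ---------------------------------------------------------------------------
# average information
# ---------------------------------------------------------------------------

def test_average_information_single_step():
    info = average_information_gaussian([[1.0]], Z=1.0)
    np.testing.assert_allclose(info.matrix, [[1.0]])
    np.testing.assert_allclose(info.eigvals, [1.0])


def test_average_information_hand_average():
    info = average_information_gaussian([[1.0, 0.0], [1.0, 2.0]], Z=1.0)
    np.testing.assert_allclose(info.matrix, [[1.0, 1.0], [1.0, 2.0]])


def test_average_information_rank_deficient_raises():
    # constant zero velocity: regressor [1, 0, 0] has rank 1
    V = np.tile([1.0, 0.0, 0.0], (50, 1))
    with pytest.raises(np.linalg.LinAlgError):
        average_information_gaussian(V, Z=350.0)


def test_point_process_information_basics():
    info = average_information_point_process([[1.0]], phi_star=[0.0], delta=1.0)
    np.testing.assert_allclose(info.matrix, [[1.0]])
    # linear in delta
    V = np.column_stack([np.ones(20), np.linspace(-1, 1, 20)])
    phi = [np.log(10.0), 0.3]
    a = average_information_point_process(V, phi, delta=0.001)
    b = average_information_point_process(V, phi, delta=0.002)
    np.testing.assert_allclose(2 * a.matrix, b.matrix, rtol=1e-12)


def test_point_process_matches_gaussian_structure(rng):
    """With a flat intensity, lambda*delta plays the role of 1/Z exactly."""
    V = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
    lam, delta = 20.0, 0.001
    pp = average_information_point_process(V, [np.log(lam), 0.0, 0.0], delta)
    ga = average_information_gaussian(V, Z=1.0 / (lam * delta))
    np.testing.assert_allclose(pp.matrix, ga.matrix, rtol=1e-12)


def test_eigensystem_reconstruction(rng):
    V = np.column_stack([np.ones(200), rng.normal(size=(200, 2))])
    info = average_information_gaussian(V, Z=350.0)
    recon = (info.eigvecs * info.eigvals) @ info.eigvecs.T
    np.testing.assert_allclose(recon, info.matrix, atol=1e-10)
    assert np.all(np.diff(info.eigvals) >= 0)


# ---------------------------------------------------------------------------
# kappa and the forward maps
# ---------------------------------------------------------------------------

def test_kappa_closed_form_value():
    assert kappa(1.0, 4.0) == pytest.approx(2 * np.sqrt(2) - 2, abs=1e-12)


@given(st.floats(1e-6, 1e3), st.floats(1e-9, 1e2))
@settings(max_examples=200, deadline=None)
def test_kappa_is_riccati_fixed_point(h, s):
    """kappa solves k = 1/(1/(k+s) + h), the scalar steady-state Riccati map."""
    k = kappa(h, s)
    assert k > 0
    assert k == pytest.approx(1.0 / (1.0 / (k + s) + h), rel=1e-10)


def test_kappa_vanishes_with_rate():
    assert kappa(1.0, 1e-16) < 1e-7


def test_steady_state_covariance_closed_forms():
    info = info_from_eigs([1.0])
    np.testing.assert_allclose(steady_state_covariance(info, 4.0),
                               [[1 / np.sqrt(2)]], rtol=1e-12)
    info2 = info_from_eigs([1.0, 2.0])
    np.testing.assert_allclose(steady_state_covariance(info2, 1.0),
                               np.diag([1 / np.sqrt(5), 1 / np.sqrt(12)]),
                               rtol=1e-12)


def test_steady_state_two_algebraic_forms_agree(rng):
    """(k^2 + s k)/(2k + s) equals 1/sqrt(h^2 + 4h/s)."""
    for _ in range(50):
        h = 10.0 ** rng.uniform(-6, 2)
        s = 10.0 ** rng.uniform(-8, 1)
        k = kappa(h, s)
        lhs = (k * k + s * k) / (2 * k + s)
        rhs = 1.0 / np.sqrt(h * h + 4 * h / s)
        assert lhs == pytest.approx(rhs, rel=1e-10)


def test_steady_state_covariance_monte_carlo_scalar(rng):
    """Constant-regressor scalar KF reaches the predicted error variance."""
    h_inv_Z, s, Z = 1.0, 0.05, 1.0  # v=1 each step
    info = info_from_eigs([1.0 / Z])
    pred = steady_state_covariance(info, s)[0, 0]
    k = kappa(1.0 / Z, s)
    reps, T = 4000, 200
    err = np.full(reps, 0.0)
    P = k  # start at steady state
    rngs = np.random.default_rng(5)
    est = np.zeros(reps)
    truth = 1.3
    est[:] = truth  # start exact; steady-state fluctuation builds up
    for t in range(T):
        P_pred = P + s
        gain = P_pred / (Z + P_pred)
        y = truth + rngs.normal(size=reps)
        est = est + gain * (y - est)
        P = P_pred - gain * P_pred
    emp = np.var(truth - est)
    assert emp == pytest.approx(pred, rel=0.10)


def test_convergence_factor_closed_form():
    info = info_from_eigs([1.0])
    assert convergence_factor(info, 0.5) == pytest.approx(0.5, rel=1e-12)
    # the two printed forms agree
    for h1, s in [(2.0, 0.3), (1e-4, 1e-5), (5.0, 2.0)]:
        rho = convergence_factor(info_from_eigs([h1]), s)
        alt = 1 - (np.sqrt(h1**2 * s**2 + 4 * h1 * s) - h1 * s) / 2
        # alt form is stated for h1-normalized dynamics; equality holds via kappa
        k = kappa(h1, s)
        assert rho == pytest.approx(k / (k + s), rel=1e-12)


def test_convergence_factor_no_adaptation_limit():
    info = info_from_eigs([1.0])
    assert convergence_factor(info, 1e-12) > 0.999998


def test_error_decay_map_asymptotic_rate(rng):
    """Iterating the full decay map contracts at the dominant factor rho."""
    U = random_orthogonal(3, rng)
    info = info_from_eigs([0.5, 1.0, 4.0], U)
    s = 0.3
    M = error_decay_map(info, s)
    rho = convergence_factor(info, s)
    g = rng.normal(size=3)
    for _ in range(200):
        g = M @ g
    g_next = M @ g
    assert np.linalg.norm(g_next) / np.linalg.norm(g) == pytest.approx(rho, rel=1e-6)


def test_predict_convergence_time_values():
    info = info_from_eigs([1.0])
    s_half = rate_for_time_bound(1.0, 1.0, e_rest=0.5, delta=1.0)
    assert predict_convergence_time(info, s_half, e_rest=0.5, delta=1.0) == pytest.approx(1.0)
    assert predict_convergence_time(info, s_half, e_rest=0.05, delta=1.0) == pytest.approx(
        np.log(0.05) / np.log(0.5), rel=1e-10)


# ---------------------------------------------------------------------------
# inverse maps
# ---------------------------------------------------------------------------

def test_rate_for_error_bound_closed_forms():
    assert rate_for_error_bound(1.0, 1 / np.sqrt(2)) == pytest.approx(4.0, rel=1e-10)
    assert rate_for_error_bound(2.0, 0.25) == pytest.approx(8.0 / 12.0, rel=1e-10)


def test_rate_for_error_bound_infeasible():
    with pytest.raises(ValueError):
        rate_for_error_bound(1.0, 1.0)


def test_error_bound_round_trip(rng):
    """Eq-9 rate plugged back into the covariance map returns V_bd exactly."""
    for _ in range(25):
        h1 = 10.0 ** rng.uniform(-5, 1)
        v_bd = rng.uniform(0.05, 0.95) / h1
        s = rate_for_error_bound(h1, v_bd)
        info = info_from_eigs([h1, 3 * h1])
        norm = np.linalg.norm(steady_state_covariance(info, s), 2)
        assert norm == pytest.approx(v_bd, rel=1e-8)


def test_rate_for_time_bound_values():
    assert rate_for_time_bound(1.0, 1.0, e_rest=0.5, delta=1.0) == pytest.approx(0.5)
    assert rate_for_time_bound(1.0, 2.0, e_rest=0.25, delta=1.0) == pytest.approx(0.5)


def test_time_bound_round_trip(rng):
    """rho(s)^(C_bd/delta) returns E_rest to 1e-10."""
    for _ in range(25):
        h1 = 10.0 ** rng.uniform(-5, 1)
        c_bd = 10.0 ** rng.uniform(0, 3)
        e_rest = rng.uniform(0.01, 0.5)
        delta = 10.0 ** rng.uniform(-3, 0)
        s = rate_for_time_bound(h1, c_bd, e_rest, delta)
        rho = convergence_factor(info_from_eigs([h1]), s)
        assert rho ** (c_bd / delta) == pytest.approx(e_rest, rel=1e-9)
        # and the predicted time equals the bound
        t = predict_convergence_time(info_from_eigs([h1]), s, e_rest, delta)
        assert t == pytest.approx(c_bd, rel=1e-9)


# ---------------------------------------------------------------------------
# monotonicity, asymptotics, symmetry
# ---------------------------------------------------------------------------

def test_monotonicity_over_six_decades(rng):
    U = random_orthogonal(3, rng)
    info = info_from_eigs([3e-4, 4e-4, 3e-3], U)
    grid = np.geomspace(1e-8, 1e-2, 61)
    diags = np.stack([np.diag(info.eigvecs.T @ steady_state_covariance(info, s)
                              @ info.eigvecs) for s in grid])
    assert np.all(np.diff(diags, axis=0) > 0), "every covariance eigenvalue grows with s"
    rhos = np.array([convergence_factor(info, s) for s in grid])
    assert np.all(np.diff(rhos) < 0), "convergence factor strictly decreases with s"


def test_small_rate_asymptotics():
    info = info_from_eigs([2e-4, 1e-3])
    s = 1e-8
    diag = np.diag(steady_state_covariance(info, s))
    np.testing.assert_allclose(diag, np.sqrt(s / (4 * info.eigvals)), rtol=1e-3)


def test_kf_ppf_structural_symmetry(rng):
    """Spike-side calibration reuses the same kernel: Eq 19 == Eq 7 under
    (h -> a, s -> r)."""
    V = np.column_stack([np.ones(100), rng.normal(scale=0.4, size=(100, 2))])
    phi = [np.log(15.0), 0.8, -0.3]
    pp = average_information_point_process(V, phi, delta=0.001)
    ga = AverageInformation.from_matrix(pp.matrix)  # same matrix through KF path
    for r in (1e-7, 1e-5, 1e-3):
        np.testing.assert_allclose(steady_state_covariance(pp, r),
                                   steady_state_covariance(ga, r), atol=1e-14)


# ---------------------------------------------------------------------------
# conservative selection and the admissible interval
# ---------------------------------------------------------------------------

def _ctx(V):
    return {"h1_of": lambda Z: average_information_gaussian(V, Z).h1,
            "e_rest": 0.05, "delta": 0.1}


def test_conservative_rate_degenerate_range(rng):
    V = np.column_stack([np.ones(200), rng.normal(scale=0.4, size=(200, 2))])
    ctx = _ctx(V)
    lone = rate_for_error_bound(ctx["h1_of"](350.0), 0.5)
    assert conservative_rate(350.0, 350.0, "error_bound", 0.5, ctx) == pytest.approx(lone)


def test_conservative_rate_is_extremal_over_grid(rng):
    V = np.column_stack([np.ones(200), rng.normal(scale=0.4, size=(200, 2))])
    ctx = _ctx(V)
    chosen = conservative_rate(320.0, 380.0, "error_bound", 0.5, ctx)
    grid = [rate_for_error_bound(ctx["h1_of"](z), 0.5)
            for z in np.linspace(320, 380, 13)]
    assert chosen == pytest.approx(min(grid), rel=1e-12)
    assert all(chosen <= g + 1e-15 for g in grid)
    chosen_t = conservative_rate(320.0, 380.0, "time_bound", 120.0, ctx)
    grid_t = [rate_for_time_bound(ctx["h1_of"](z), 120.0, 0.05, 0.1)
              for z in np.linspace(320, 380, 13)]
    assert chosen_t == pytest.approx(max(grid_t), rel=1e-12)


def test_selected_rate_monotone_in_Z(rng):
    """Basis of the conservative rule: the rate is monotone in the noise."""
    V = np.column_stack([np.ones(200), rng.normal(scale=0.4, size=(200, 2))])
    ctx = _ctx(V)
    rates = [rate_for_error_bound(ctx["h1_of"](z), 0.5)
             for z in np.linspace(320.0, 380.0, 16)]
    diffs = np.diff(rates)
    assert np.all(diffs < 0) or np.all(diffs > 0)


def test_admissible_interval_contract(rng):
    V = np.column_stack([np.ones(400), rng.normal(scale=0.4, size=(400, 2))])
    info = average_information_gaussian(V, Z=350.0)
    delta = 0.1
    out = admissible_interval(info, v_bd=0.9 / info.h1, c_bd=500.0,
                              e_rest=0.05, delta=delta)
    assert out is not None
    s_lo, s_hi = out
    assert s_lo < s_hi
    for s in np.geomspace(s_lo, s_hi, 5):
        assert np.linalg.norm(steady_state_covariance(info, s), 2) <= 0.9 / info.h1 * (1 + 1e-9)
        assert predict_convergence_time(info, s, 0.05, delta) <= 500.0 * (1 + 1e-9)
    # tighten the error bound until the interval empties: no exception, None out
    tight = admissible_interval(info, v_bd=1e-4 / info.h1, c_bd=500.0,
                                e_rest=0.05, delta=delta)
    assert tight is None


def test_calibrator_estimator_interface(rng):
    V = rng.normal(scale=0.4, size=(500, 2))
    cal = LearningRateCalibrator(kind="gaussian", Z=(320.0, 380.0), delta=0.1,
                                 v_bd=0.4)
    cal.fit(V)
    assert 0 < cal.learning_rate_
    assert cal.result_.predicted_factor < 1
    # sklearn-style params round trip
    assert cal.set_params(**cal.get_params()).get_params()["v_bd"] == 0.4
    # conservative choice never exceeds either endpoint's rate
    for z in (320.0, 380.0):
        single = LearningRateCalibrator(kind="gaussian", Z=z, delta=0.1,
                                        v_bd=0.4).fit(V)
        assert cal.learning_rate_ <= single.learning_rate_ * (1 + 1e-12)
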