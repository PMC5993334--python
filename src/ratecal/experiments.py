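"""Monte-Carlo validation harness: rate sweeps, coverage, decode-freeze.

The harness generates center-out-and-back sessions with the OFC subject model,
runs the adaptive filters over ensembles of simulated channels at each
learning rate, and compares the empirical steady-state error covariance and
convergence time against the analytic predictions of the calibration engine.

Estimating the *expected* error trajectory ``E[g_t]`` from simulation requires
noise cancellation: replicate runs share the true parameters and the initial
estimates but use independent observation noise, the per-channel error vectors
are normalized by their initial norm and averaged over channels and
replicates, and the convergence time is the first threshold crossing of the
norm of that average (with a short dwell against noise-induced early
crossings).  Steady-state covariances are pooled per channel over the final
window of each run and averaged over channels and replicates in the parameter
basis.

Problem sizes are scaled down from exhaustive sweeps: each rate runs for about
six predicted convergence times (so the final third of the session is
comfortably at steady state), and the replicate count grows with the predicted
steady-state error so that the noise floor of the expected-error estimate
stays well below the 5 % convergence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from . import _batch
from .calibration import (
    AverageInformation,
    average_information_point_process,
    convergence_factor,
    kappa,
    predict_convergence_time,
    steady_state_covariance,
)
from .models import (
    GaussianEnsembleSpec,
    PointProcessEnsembleSpec,
    sample_channel_ensemble,
)
from .ofc import (
    OFCCost,
    TaskConfig,
    default_cost,
    default_dynamics,
    generate_session,
    lqg_gain,
    peak_reach_speed,
)

__all__ = [
    "Scenario",
    "PRESETS",
    "SweepResult",
    "DecodeFreezeResult",
    "ConvergenceTime",
    "empirical_error_covariance",
    "empirical_convergence_time",
    "normalized_rmse",
    "ci_coverage",
    "decoding_rmse",
    "run_rate_sweep",
    "run_coverage",
    "run_convergence_probe",
    "run_decode_freeze",
    "run_day_shift",
    "KF_RATE_GRID",
    "PPF_RATE_GRID",
]

E_REST = 0.05          #: relative-error threshold defining convergence
DWELL_STEPS = 10       #: steps the error must stay below threshold
SESSION_FACTOR = 6.0   #: session length in predicted convergence times
STEADY_FRACTION = 1.0 / 3.0  #: final fraction of the session treated as steady state

KF_RATE_GRID = np.geomspace(5e-6, 5e-4, 8)
PPF_RATE_GRID = np.geomspace(1e-7, 1e-4, 8)


@dataclass(frozen=True)
class Scenario:
    """A named simulation condition for the validation experiments."""

    kind: str = "gaussian"              # 'gaussian' or 'spikes'
    order: str = "counter_clockwise"    # or 'uniform_random'
    concurrent_Z: bool = False
    n_channels: int = 30
    delta: float = 0.1                  # seconds per bin
    window_L: int = 200                 # covariance-matching window
    n_targets: int = 8
    radius: float = 0.3
    trial_duration: float = 2.0
    cost: OFCCost = field(default_factory=default_cost)
    noise_std: float | None = None      # OFC velocity noise SD (None = default)
    velocity_tau: float | None = None   # override of the velocity time constant


PRESETS = {
    "kf_periodic": Scenario(kind="gaussian", order="counter_clockwise"),
    "kf_random_targets": Scenario(kind="gaussian", order="uniform_random"),
    "kf_joint_Z": Scenario(kind="gaussian", order="counter_clockwise", concurrent_Z=True),
    "kf_joint_Z_random": Scenario(kind="gaussian", order="uniform_random", concurrent_Z=True),
    "ppf_periodic": Scenario(kind="spikes", order="counter_clockwise", delta=0.001),
    "ppf_random_targets": Scenario(kind="spikes", order="uniform_random", delta=0.001),
}


class ConvergenceTime(NamedTuple):
    seconds: float
    converged: bool


# ---------------------------------------------------------------------------
# Spec'd measurement operations on adaptation traces
# ---------------------------------------------------------------------------

def empirical_error_covariance(traces, steady_window: float = 0.3) -> np.ndarray:
    """Steady-state error covariance from adaptation traces.

    ``traces`` is one :class:`~ratecal.filters.AdaptationTrace` or a list of
    them; per-channel sample covariances of ``truth - mean`` over the final
    ``steady_window`` fraction are averaged in the parameter basis.
    """
    if not isinstance(traces, (list, tuple)):
        traces = [traces]
    if not (0 < steady_window <= 1):
        raise ValueError("steady_window must be in (0, 1]")
    covs = []
    for tr in traces:
        errs = tr.errors()
        start = int(np.floor(len(errs) * (1 - steady_window)))
        window = errs[start:]
        if len(window) < 10:
            raise ValueError("steady-state window shorter than 10 samples")
        covs.append(np.cov(window.T, ddof=1))
    return np.mean(covs, axis=0)


def empirical_convergence_time(traces, e_rest: float = E_REST,
                               delta: float | None = None,
                               dwell: int = DWELL_STEPS) -> ConvergenceTime:
    """First time the ensemble-averaged relative error stays below ``e_rest``.

    Per-channel error vectors are normalized by their initial norm, averaged
    over channels, and the norm of the average is thresholded with a
    ``dwell``-step persistence requirement.
    """
    if not (0 < e_rest < 1):
        raise ValueError("e_rest must be in (0, 1)")
    if not isinstance(traces, (list, tuple)):
        traces = [traces]
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if delta is None:
        delta = traces[0].delta
    rel = None
    for tr in traces:
        errs = tr.errors()
        n0 = np.linalg.norm(errs[0])
        if n0 == 0:
            raise ValueError("trace starts exactly at the truth")
        r = np.linalg.norm(errs, axis=1) / n0
        rel = r if rel is None else rel + r
    rel = rel / len(traces)
    return _first_crossing(rel, e_rest, delta, dwell)


def _first_crossing(rel: np.ndarray, e_rest: float, delta: float,
                    dwell: int) -> ConvergenceTime:
    below = rel <= e_rest
    if dwell > 1:
        kernel = np.ones(dwell, dtype=int)
        runs = np.convolve(below.astype(int), kernel, mode="valid")
        idx = np.nonzero(runs == dwell)[0]
    else:
        idx = np.nonzero(below)[0]
    if len(idx) == 0:
        return ConvergenceTime(seconds=len(rel) * delta, converged=False)
    return ConvergenceTime(seconds=float(idx[0] * delta), converged=True)


def normalized_rmse(analytic_curve, empirical_curve) -> float:
    """RMSE between two curves divided by the empirical curve's range."""
    a = np.asarray(analytic_curve, dtype=float)
    e = np.asarray(empirical_curve, dtype=float)
    if a.shape != e.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("curves must be equal-length 1-D with >= 2 points")
    rng = e.max() - e.min()
    if rng <= 0:
        raise ValueError("empirical curve has zero range")
    return float(np.sqrt(np.mean((a - e) ** 2)) / rng)


def ci_coverage(trace, analytic_cov: np.ndarray, steady_window: float = 0.3) -> float:
    """Fraction of steady-state (step, parameter) pairs within +-2 analytic SD."""
    errs = trace.errors()
    start = int(np.floor(len(errs) * (1 - steady_window)))
    window = errs[start:]
    if len(window) < 10:
        raise ValueError("steady-state window shorter than 10 samples")
    bounds = 2.0 * np.sqrt(np.diag(np.asarray(analytic_cov, dtype=float)))
    return float(np.mean(np.abs(window) <= bounds[None, :]))


def decoding_rmse(decoded_positions, trial_segments) -> float:
    """RMS perpendicular distance of decoded positions to the reach lines.

    ``trial_segments`` is a list of ``(start, end, target_xy)`` with the
    peripheral target defining the center-target supporting line for the whole
    trial (out and back).
    """
    decoded_positions = np.asarray(decoded_positions, dtype=float)
    if len(trial_segments) == 0:
        raise ValueError("no trial segments given")
    sq = []
    for start, end, target in trial_segments:
        if not (0 <= start < end <= len(decoded_positions)):
            raise ValueError("segment outside session bounds")
        target = np.asarray(target, dtype=float)
        norm = np.linalg.norm(target)
        if norm == 0:
            raise ValueError("degenerate target at the center")
        that = target / norm
        pos = decoded_positions[start:end]
        dist = pos[:, 0] * that[1] - pos[:, 1] * that[0]
        sq.append(dist**2)
    return float(np.sqrt(np.mean(np.concatenate(sq))))


# ---------------------------------------------------------------------------
# Scenario setup
# ---------------------------------------------------------------------------

@dataclass
class _Setup:
    scenario: Scenario
    task: TaskConfig
    dyn: object
    truth: np.ndarray      # (C, 3) true parameters
    init: np.ndarray       # (C, 3) initial estimates
    Z: np.ndarray          # (C,) noise variances (gaussian) or zeros
    infos: list            # per-channel AverageInformation
    session_V: np.ndarray  # (T_ref, 3) reference regressors
    steps_per_trial: int
    init_cov: float
    rep_seeds: np.ndarray


def _scenario(preset) -> Scenario:
    if isinstance(preset, Scenario):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}") from None


def _scenario_dynamics(sc: Scenario):
    """Kinematic model for a scenario, honoring its overrides."""
    from .ofc import VELOCITY_TAU, LinearDynamics, calibrated_noise_std

    if sc.velocity_tau is None and sc.noise_std is None:
        return default_dynamics(sc.delta)
    tau = sc.velocity_tau if sc.velocity_tau is not None else VELOCITY_TAU
    alpha = float(np.exp(-sc.delta / tau))
    noise_std = (sc.noise_std if sc.noise_std is not None
                 else calibrated_noise_std(sc.delta))
    A = np.array([[1, 0, sc.delta, 0], [0, 1, 0, sc.delta],
                  [0, 0, alpha, 0], [0, 0, 0, alpha]])
    B = np.array([[0, 0], [0, 0], [1, 0], [0, 1]], dtype=float)
    W = np.zeros((4, 4))
    W[2, 2] = W[3, 3] = noise_std**2
    return LinearDynamics(A=A, B=B, W=W, delta=sc.delta, alpha_decay=alpha)


def _setup_scenario(preset, seed: int, n_ref_trials: int = 200,
                    max_reps: int = 128) -> _Setup:
    sc = _scenario(preset)
    ss = np.random.SeedSequence([int(seed), 0x5CA1AB1E])
    kids = ss.spawn(4)
    rng_ens = np.random.default_rng(kids[0])
    rng_init = np.random.default_rng(kids[1])
    rng_session = np.random.default_rng(kids[2])
    rep_seeds = kids[3].generate_state(max_reps, dtype=np.uint32) % np.uint32(2**31)

    dyn = _scenario_dynamics(sc)
    task = TaskConfig(n_targets=sc.n_targets, radius=sc.radius,
                      trial_duration=sc.trial_duration, order=sc.order,
                      n_trials=n_ref_trials)
    spt = task.steps_per_trial(sc.delta)

    if sc.kind == "gaussian":
        spec = GaussianEnsembleSpec()
        ens = sample_channel_ensemble(spec, sc.n_channels, rng_ens)
        ens0 = sample_channel_ensemble(spec, sc.n_channels, rng_init)
        truth = np.stack([m.psi() for m in ens])
        init = np.stack([m.psi() for m in ens0])
        Z = np.array([m.Z for m in ens])
        init_cov = 1.0
    elif sc.kind == "spikes":
        v_max = peak_reach_speed(sc.delta, sc.cost, sc.radius)
        spec = PointProcessEnsembleSpec(delta=sc.delta, v_max=v_max)
        ens = sample_channel_ensemble(spec, sc.n_channels, rng_ens)
        ens0 = sample_channel_ensemble(spec, sc.n_channels, rng_init)
        truth = np.stack([m.phi() for m in ens])
        init = np.stack([m.phi() for m in ens0])
        Z = np.zeros(sc.n_channels)
        init_cov = 1e-2
    else:
        raise ValueError(f"unknown scenario kind {sc.kind!r}")

    kin = generate_session(task, dyn, sc.cost, rng_session)
    V = kin.regressors()
    if sc.kind == "gaussian":
        G = V.T @ V / len(V)
        infos = [AverageInformation.from_matrix(G / z) for z in Z]
    else:
        infos = [average_information_point_process(V, truth[c], sc.delta)
                 for c in range(sc.n_channels)]
    return _Setup(scenario=sc, task=task, dyn=dyn, truth=truth, init=init, Z=Z,
                  infos=infos, session_V=V, steps_per_trial=spt,
                  init_cov=init_cov, rep_seeds=rep_seeds)


def _session_regressors(setup: _Setup, n_steps: int, rng=None) -> np.ndarray:
    """Regressors for a session of at least ``n_steps`` steps.

    The reference session is reused (and extended if needed) so that all
    learning rates see the same kinematics — common random numbers across the
    sweep.
    """
    V = setup.session_V
    if len(V) < n_steps:
        raise ValueError(
            "reference session shorter than requested; increase n_ref_trials"
        )
    return V[:n_steps]


def _predicted_steps(setup: _Setup, rate: float) -> int:
    times = [predict_convergence_time(info, rate, E_REST, setup.scenario.delta)
             for info in setup.infos]
    return int(np.ceil(max(times) / setup.scenario.delta))


def _analytic_summaries(setup: _Setup, rate: float):
    covs = np.stack([steady_state_covariance(info, rate) for info in setup.infos])
    mean_cov = covs.mean(axis=0)
    times = [predict_convergence_time(info, rate, E_REST, setup.scenario.delta)
             for info in setup.infos]
    return covs, float(np.linalg.norm(mean_cov, 2)), float(np.mean(times))


def _steady_init_cov(setup: _Setup, rate: float) -> np.ndarray:
    """Per-channel steady-state posterior covariance ``U diag(kappa_m) U'``.

    The analytic error dynamics hold once the filter covariance has settled on
    its periodic steady state; starting the filter there removes the initial
    covariance transient, so the measured 5 %-crossing time estimates the
    geometric decay the theory describes rather than the transient of an
    arbitrary initial confidence.
    """
    out = np.empty((len(setup.infos), 3, 3))
    for c, info in enumerate(setup.infos):
        k = np.array([kappa(h, rate) for h in info.eigvals])
        U = info.eigvecs
        out[c] = (U * k) @ U.T
    return out


def _reps_for_rate(setup: _Setup, covs: np.ndarray, floor: float = 0.02,
                   min_reps: int = 2, max_reps: int = 48) -> int:
    tr = float(np.mean([np.trace(c) for c in covs]))
    g0sq = float(np.mean(np.sum((setup.truth - setup.init) ** 2, axis=1)))
    need = tr / (floor**2 * g0sq)
    return int(np.clip(np.ceil(need), min_reps, max_reps))


# ---------------------------------------------------------------------------
# Rate sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-rate analytic and empirical summaries of one sweep."""

    rates: np.ndarray
    analytic_cov_norm: np.ndarray
    empirical_cov_norm: np.ndarray
    analytic_conv_time: np.ndarray
    empirical_conv_time: np.ndarray
    converged: np.ndarray
    coverage: np.ndarray
    Z_ratio: np.ndarray | None = None   # mean final Z estimate / true Z
    reps: np.ndarray | None = None
    session_steps: np.ndarray | None = None

    def nrmse_covariance(self) -> float:
        return normalized_rmse(self.analytic_cov_norm, self.empirical_cov_norm)

    def nrmse_convergence_time(self) -> float:
        return normalized_rmse(self.analytic_conv_time, self.empirical_conv_time)

    def to_frame(self):
        import pandas as pd

        data = {
            "rate": self.rates,
            "analytic_cov_norm": self.analytic_cov_norm,
            "empirical_cov_norm": self.empirical_cov_norm,
            "analytic_conv_time_s": self.analytic_conv_time,
            "empirical_conv_time_s": self.empirical_conv_time,
            "converged": self.converged,
            "coverage": self.coverage,
        }
        if self.Z_ratio is not None:
            data["Z_ratio"] = self.Z_ratio
        return pd.DataFrame(data)


def _run_rate(setup: _Setup, rate: float, reps: int, bounds: np.ndarray,
              n_steps: int, win_start: int, z_init: float | None):
    sc = setup.scenario
    V = _session_regressors(setup, n_steps)
    C, n = setup.truth.shape
    g_sum = np.zeros((C, n))
    gg_sum = np.zeros((C, n, n))
    thin = max(1, n_steps // 150_000)
    err_acc = np.zeros((-(-n_steps // thin), C, n), dtype=np.float32)
    n_in = 0
    n_tot = 0
    z_final = np.zeros(C)
    psi_final = np.zeros((C, n))
    S0 = _steady_init_cov(setup, rate)
    for rep in range(reps):
        seed = int(setup.rep_seeds[rep])
        if sc.kind == "gaussian":
            ni, nt, zf, pf = _batch.kf_adapt_batch(
                V, setup.truth, setup.init, setup.Z, float(rate),
                S0, seed, win_start, bounds,
                sc.concurrent_Z, sc.window_L,
                float(z_init if z_init is not None else 350.0),
                g_sum, gg_sum, err_acc, thin)
            z_final += zf
        else:
            ni, nt, pf = _batch.ppf_adapt_batch(
                V, setup.truth, setup.init, sc.delta, float(rate),
                S0, seed, win_start, bounds,
                g_sum, gg_sum, err_acc, thin)
        n_in += ni
        n_tot += nt
        psi_final = pf
    n_win = reps * (n_steps - win_start)
    mean_err = g_sum / n_win
    cov = gg_sum / n_win - np.einsum("ci,cj->cij", mean_err, mean_err)
    mean_cov = cov.mean(axis=0)
    # expected-error decay: replicate-averaged error vectors, per-channel norms
    # normalized by the initial error, averaged over channels
    norm0 = np.linalg.norm(setup.truth - setup.init, axis=1)
    rel = np.linalg.norm(err_acc / reps, axis=2) / norm0[None, :]
    rel = rel.mean(axis=1)
    conv = _first_crossing(rel, E_REST, sc.delta * thin, DWELL_STEPS)
    out = dict(
        cov_norm=float(np.linalg.norm(mean_cov, 2)),
        conv_time=conv.seconds, converged=conv.converged,
        coverage=n_in / n_tot, final_params=psi_final,
    )
    if sc.kind == "gaussian" and sc.concurrent_Z:
        out["Z_ratio"] = float(np.mean(z_final / reps / setup.Z))
    return out


def run_rate_sweep(preset, rate_grid=None, reps: int | None = None,
                   seed: int = 0, max_steps: int | None = None,
                   rep_floor: float = 0.02, max_reps: int = 48) -> SweepResult:
    """Adaptive-filter sweep over a learning-rate grid for one scenario.

    For every rate the session runs for about ``SESSION_FACTOR`` predicted
    convergence times (common kinematics and common noise seeds across rates),
    and empirical convergence time, steady-state covariance, coverage and (for
    concurrent-Z scenarios) the noise-variance estimate are measured and set
    against the analytic predictions.
    """
    sc = _scenario(preset)
    if max_steps is None:
        max_steps = 600_000 if sc.kind == "gaussian" else 2_400_000
    if rate_grid is None:
        rate_grid = KF_RATE_GRID if sc.kind == "gaussian" else PPF_RATE_GRID
    rate_grid = np.sort(np.asarray(rate_grid, dtype=float))

    # size the reference session from the smallest (slowest) rate
    setup = _setup_scenario(sc, seed, n_ref_trials=64)
    n_needed = int(SESSION_FACTOR * _predicted_steps(setup, rate_grid[0])) + 1
    n_trials = min(int(np.ceil(n_needed / setup.steps_per_trial)) + 1,
                   int(np.ceil(max_steps / setup.steps_per_trial)))
    setup = _setup_scenario(sc, seed, n_ref_trials=max(n_trials, 64))

    rows = []
    rep_list, step_list = [], []
    fixed_reps = reps
    z_init = float(np.mean([320.0, 380.0])) if sc.concurrent_Z else None
    for rate in rate_grid:
        covs, a_norm, a_time = _analytic_summaries(setup, rate)
        n_star = _predicted_steps(setup, rate)
        n_steps = min(int(np.ceil(SESSION_FACTOR * n_star)), max_steps,
                      len(setup.session_V))
        win_start = int(np.floor(n_steps * (1 - STEADY_FRACTION)))
        if sc.kind == "gaussian" and not sc.concurrent_Z and fixed_reps is None:
            r = _reps_for_rate(setup, covs, rep_floor, max_reps=max_reps)
        else:
            r = fixed_reps if fixed_reps is not None else 3
        bounds = 2.0 * np.sqrt(np.stack([np.diag(c) for c in covs]))
        res = _run_rate(setup, rate, r, bounds, n_steps, win_start, z_init)
        rows.append((a_norm, a_time, res))
        rep_list.append(r)
        step_list.append(n_steps)

    return SweepResult(
        rates=rate_grid,
        analytic_cov_norm=np.array([r[0] for r in rows]),
        empirical_cov_norm=np.array([r[2]["cov_norm"] for r in rows]),
        analytic_conv_time=np.array([r[1] for r in rows]),
        empirical_conv_time=np.array([r[2]["conv_time"] for r in rows]),
        converged=np.array([r[2]["converged"] for r in rows]),
        coverage=np.array([r[2]["coverage"] for r in rows]),
        Z_ratio=(np.array([r[2]["Z_ratio"] for r in rows])
                 if sc.concurrent_Z else None),
        reps=np.array(rep_list),
        session_steps=np.array(step_list),
    )


# ---------------------------------------------------------------------------
# Coverage and convergence probes
# ---------------------------------------------------------------------------

def run_coverage(preset, rates, seed: int = 0, session_factor: float = 4.0,
                 max_steps: int | None = None) -> dict:
    """Pooled +-2-SD coverage of steady-state estimates at selected rates."""
    sc = _scenario(preset)
    if max_steps is None:
        max_steps = 600_000 if sc.kind == "gaussian" else 2_400_000
    rates = np.asarray(rates, dtype=float)
    setup = _setup_scenario(sc, seed, n_ref_trials=64)
    n_needed = int(session_factor * _predicted_steps(setup, rates.min())) + 1
    n_trials = min(int(np.ceil(n_needed / setup.steps_per_trial)) + 1,
                   int(np.ceil(max_steps / setup.steps_per_trial)))
    setup = _setup_scenario(sc, seed, n_ref_trials=max(n_trials, 64))
    n_in = 0
    n_tot = 0
    per_rate = []
    for rate in rates:
        covs, _, _ = _analytic_summaries(setup, rate)
        n_star = _predicted_steps(setup, rate)
        n_steps = min(int(np.ceil(session_factor * n_star)), max_steps,
                      len(setup.session_V))
        win_start = n_steps // 2
        bounds = 2.0 * np.sqrt(np.stack([np.diag(c) for c in covs]))
        res = _run_rate(setup, rate, 1, bounds, n_steps, win_start, None)
        per_rate.append(res["coverage"])
        frac = res["coverage"]
        n = n_steps - win_start
        n_in += frac * n
        n_tot += n
    return {"coverage": float(n_in / n_tot),
            "per_rate": np.array(per_rate), "rates": rates}


def destabilizing_rate(preset, seed: int = 0, sd_multiple: float = 1.5) -> float:
    """Learning rate whose predicted steady error SD is ``sd_multiple`` times
    the mean modulation depth — i.e. a rate that is clearly too large for the
    task, useful as the 'very large' condition in decode-freeze experiments.

    Derived from the analytic map (the error-bound inverse evaluated at a
    covariance norm of ``(sd_multiple * depth)^2``), so 'too large' is defined
    relative to the task's information scale rather than by an absolute
    number.
    """
    from .calibration import rate_for_error_bound

    setup = _setup_scenario(_scenario(preset), seed, n_ref_trials=64)
    depth = float(np.mean(np.linalg.norm(setup.truth[:, 1:], axis=1)))
    h1 = float(np.mean([info.h1 for info in setup.infos]))
    return rate_for_error_bound(h1, (sd_multiple * depth) ** 2)


def run_convergence_probe(preset, rate: float, seed: int = 0, reps: int = 3,
                          max_seconds: float = 2000.0) -> ConvergenceTime:
    """Time for the expected parameter error to first reach ``E_REST``."""
    sc = _scenario(preset)
    setup = _setup_scenario(sc, seed, n_ref_trials=64)
    n_star = _predicted_steps(setup, rate)
    n_steps = min(int(np.ceil(SESSION_FACTOR * n_star)),
                  int(np.ceil(max_seconds / sc.delta)))
    n_trials = int(np.ceil(n_steps / setup.steps_per_trial)) + 1
    setup = _setup_scenario(sc, seed, n_ref_trials=max(n_trials, 64))
    covs, _, _ = _analytic_summaries(setup, rate)
    bounds = 2.0 * np.sqrt(np.stack([np.diag(c) for c in covs]))
    res = _run_rate(setup, rate, reps, bounds, n_steps,
                    int(n_steps * (1 - STEADY_FRACTION)), None)
    return ConvergenceTime(seconds=res["conv_time"], converged=res["converged"])


# ---------------------------------------------------------------------------
# Decode-freeze experiments
# ---------------------------------------------------------------------------

@dataclass
class DecodeFreezeResult:
    rates: np.ndarray
    stop_times: np.ndarray
    rmse: np.ndarray  # (n_rates, n_stops, reps)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, rate in enumerate(self.rates):
            for j, stop in enumerate(self.stop_times):
                for k in range(self.rmse.shape[2]):
                    rows.append(dict(rate=rate, stop_time_s=stop, rep=k,
                                     rmse=self.rmse[i, j, k]))
        return pd.DataFrame(rows)


def _step_targets(setup: _Setup, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    task = replace(setup.task, n_trials=n_trials)
    ids = task.target_sequence(n_trials, rng if task.order == "uniform_random" else None)
    ang = task.target_angles()
    pos = task.radius * np.column_stack([np.cos(ang), np.sin(ang)])
    spt = setup.steps_per_trial
    half = spt // 2
    targets = np.zeros((n_trials * spt, 2))
    for tr in range(n_trials):
        targets[tr * spt: tr * spt + half] = pos[ids[tr]]
        # second half: return to the center (zeros)
    return targets, ids


def _fitted_decoder_noise(setup: _Setup) -> float:
    """Decoder prior velocity-noise SD fitted to the session kinematics.

    The kinematic decoder does not observe the subject's control input, so its
    random-walk-with-decay prior must absorb it: the per-axis SD of the
    realized velocity innovations ``v_{t+1} - alpha v_t`` over a reference
    session plays the role of the fitted process noise.
    """
    v = setup.session_V[:, 1:]
    innov = v[1:] - setup.dyn.alpha_decay * v[:-1]
    return float(innov.std())


def run_decode_freeze(preset, rate_grid, stop_times, eval_trials: int = 16,
                      reps: int = 4, seed: int = 0) -> DecodeFreezeResult:
    """Closed-loop adaptation frozen at several times, then pure decoding.

    For each learning rate and replicate, the encoding model adapts in closed
    loop (the OFC subject acting on the decoded cursor); at each stop time the
    parameter estimates are snapshotted, and each snapshot decoder is run
    frozen for ``eval_trials`` trials to measure the straight-line decoding
    RMSE.
    """
    sc = _scenario(preset)
    stop_times = np.asarray(sorted(stop_times), dtype=float)
    rate_grid = np.asarray(rate_grid, dtype=float)
    setup = _setup_scenario(sc, seed, n_ref_trials=64)
    dyn = setup.dyn
    L = lqg_gain(dyn, sc.cost)
    wstd = float(np.sqrt(dyn.W[2, 2]))
    dec_wstd = _fitted_decoder_noise(setup)
    v_cap = 2.0 * peak_reach_speed(sc.delta, sc.cost, sc.radius)
    spt = setup.steps_per_trial
    stop_steps = np.round(stop_times / sc.delta).astype(int)
    if np.any(stop_steps % spt != 0):
        stop_steps = (np.ceil(stop_steps / spt) * spt).astype(int)
    n_adapt_trials = int(stop_steps[-1] // spt)
    seed_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    target_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 78]))
    adapt_targets, _ = _step_targets(setup, n_adapt_trials, target_rng)
    eval_targets, eval_ids = _step_targets(setup, eval_trials, target_rng)
    eval_segments = [
        (tr * spt, (tr + 1) * spt,
         setup.task.radius * np.array([np.cos(2 * np.pi * eval_ids[tr] / sc.n_targets),
                                       np.sin(2 * np.pi * eval_ids[tr] / sc.n_targets)]))
        for tr in range(eval_trials)
    ]

    all_seeds = seed_rng.integers(0, 2**31, size=(reps, 2 * len(stop_steps)))
    rmse = np.zeros((len(rate_grid), len(stop_steps), reps))
    for i, rate in enumerate(rate_grid):
        S0 = _steady_init_cov(setup, rate)
        for k in range(reps):
            psi_hat = setup.init.copy()
            S_hat = S0.copy()
            x_dec = np.zeros(4)
            P_dec = 1e-2 * np.eye(4)
            v_int = np.zeros(2)
            prev = 0
            seeds = all_seeds[k]
            for j, stop in enumerate(stop_steps):
                seg = adapt_targets[prev:stop]
                if len(seg):
                    if sc.kind == "gaussian":
                        _batch.kf_closed_loop(
                            seg, L, sc.delta, dyn.alpha_decay, wstd, dec_wstd, v_cap,
                            setup.truth, setup.Z, float(rate), True,
                            psi_hat, S_hat, psi_hat, x_dec, P_dec, v_int,
                            int(seeds[2 * j]))
                    else:
                        _batch.ppf_closed_loop(
                            seg, L, sc.delta, dyn.alpha_decay, wstd, dec_wstd, v_cap,
                            setup.truth, float(rate), True,
                            psi_hat, S_hat, psi_hat, x_dec, P_dec, v_int,
                            int(seeds[2 * j]))
                prev = stop
                frozen = psi_hat.copy()
                ex = np.zeros(4)
                eP = 1e-2 * np.eye(4)
                ev = np.zeros(2)
                dummy_cov = np.zeros((sc.n_channels, 3, 3))
                if sc.kind == "gaussian":
                    dec, _ = _batch.kf_closed_loop(
                        eval_targets, L, sc.delta, dyn.alpha_decay, wstd,
                        dec_wstd, v_cap, setup.truth, setup.Z, 0.0, False,
                        frozen, dummy_cov, frozen, ex, eP, ev,
                        int(seeds[2 * j + 1]))
                else:
                    dec, _ = _batch.ppf_closed_loop(
                        eval_targets, L, sc.delta, dyn.alpha_decay, wstd,
                        dec_wstd, v_cap, setup.truth, 0.0, False,
                        frozen, dummy_cov, frozen, ex, eP, ev,
                        int(seeds[2 * j + 1]))
                rmse[i, j, k] = decoding_rmse(dec, eval_segments)
    return DecodeFreezeResult(rates=rate_grid, stop_times=stop_steps * sc.delta,
                              rmse=rmse)


# ---------------------------------------------------------------------------
# Day-shift re-learning
# ---------------------------------------------------------------------------

def run_day_shift(preset, rate: float, seed: int = 0,
                  session_factor: float = 4.0, reps: int | None = None) -> dict:
    """Two-day scenario: adapt to day-1 truth, shift the truth, re-adapt.

    Day 2 restarts the same filter (same calibrated rate, covariance reset)
    from the day-1 estimates.  Returns per-day convergence and coverage.
    Replicates (same truth and start, independent noise) average the error
    trajectory so its noise floor stays below the convergence threshold.
    """
    sc = _scenario(preset)
    setup = _setup_scenario(sc, seed, n_ref_trials=64)
    n_star = _predicted_steps(setup, rate)
    n_steps = int(np.ceil(session_factor * n_star))
    n_trials = int(np.ceil(n_steps / setup.steps_per_trial)) + 1
    setup = _setup_scenario(sc, seed, n_ref_trials=max(n_trials, 64))
    covs, _, _ = _analytic_summaries(setup, rate)
    if reps is None:
        reps = _reps_for_rate(setup, covs)
    bounds = 2.0 * np.sqrt(np.stack([np.diag(c) for c in covs]))
    V = setup.session_V[:n_steps]
    win_start = n_steps // 2

    rng_shift = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    days = []
    init = setup.init
    truth = setup.truth
    C, n = truth.shape
    S0 = _steady_init_cov(setup, rate)
    for day in (1, 2):
        g_sum = np.zeros((C, n))
        gg_sum = np.zeros((C, n, n))
        thin = max(1, n_steps // 150_000)
        err_acc = np.zeros((-(-n_steps // thin), C, n), dtype=np.float32)
        n_in = 0
        n_tot = 0
        for rep in range(reps):
            kseed = int(setup.rep_seeds[(day - 1) * reps + rep])
            if sc.kind == "gaussian":
                ni, nt, _, pf = _batch.kf_adapt_batch(
                    V, truth, init, setup.Z, float(rate), S0,
                    kseed, win_start, bounds, False, sc.window_L, 350.0,
                    g_sum, gg_sum, err_acc, thin)
            else:
                ni, nt, pf = _batch.ppf_adapt_batch(
                    V, truth, init, sc.delta, float(rate), S0,
                    kseed, win_start, bounds, g_sum, gg_sum, err_acc, thin)
            n_in += ni
            n_tot += nt
        norm0 = np.linalg.norm(truth - init, axis=1)
        rel = (np.linalg.norm(err_acc / reps, axis=2) / norm0[None, :]).mean(axis=1)
        conv = _first_crossing(rel, E_REST, sc.delta * thin, DWELL_STEPS)
        days.append(dict(day=day, conv_time=conv.seconds,
                         converged=conv.converged, coverage=n_in / n_tot))
        # day 2: truth shifts; the filter restarts (covariance reset) from its
        # day-1 estimates, with the same calibrated rate.
        init = pf.copy()
        if sc.kind == "gaussian":
            spec = GaussianEnsembleSpec()
            shifted = sample_channel_ensemble(spec, sc.n_channels, rng_shift)
            truth = np.stack([m.psi() for m in shifted])
        else:
            v_max = peak_reach_speed(sc.delta, sc.cost, sc.radius)
            spec = PointProcessEnsembleSpec(delta=sc.delta, v_max=v_max)
            shifted = sample_channel_ensemble(spec, sc.n_channels, rng_shift)
            truth = np.stack([m.phi() for m in shifted])
    return {"days": days}
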