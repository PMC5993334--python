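"""Center-out-and-back cursor task with an LQG optimal-feedback-control subject.

The simulated subject's kinematics follow the discrete linear model

    x_{t+1} = A x_t + B u_t + w_t,   x = [d_x, d_y, v_x, v_y]'

with position integrating velocity (``d += delta * v``), velocity persistence
``alpha`` per step, control entering the velocity rows, and process noise W in
the velocity block only.  The subject picks ``u_t = -L (x_t - x*)`` where the
gain L is the infinite-horizon LQR solution for the quadratic cost

    J = sum_t ||d_t - d*||^2 + w_v ||v_t||^2 + w_r ||u_t||^2 .

A session is a sequence of fixed-duration trials: an out-reach to one of eight
peripheral targets on a circle (radius 0.3) followed by a return to the
center, two seconds per trial, with the target order either periodic
(counter-clockwise) or i.i.d. uniform.

The cost weights, velocity time constant and noise scale are not tied to any
particular dataset; the defaults here were frozen once so that a noiseless
reach of radius 0.3 completes in about one second (so out-and-back fits the
2-s trial) and the speed fluctuation due to W is about 5 % of the peak reach
speed.  All of them are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearDynamics",
    "OFCCost",
    "TaskConfig",
    "SessionKinematics",
    "default_dynamics",
    "default_cost",
    "lqg_gain",
    "ofc_step",
    "generate_session",
    "peak_reach_speed",
    "closed_loop_session",
]

#: Velocity persistence time constant (seconds): alpha = exp(-delta / tau).
VELOCITY_TAU = 0.2

#: Frozen cost weights (independent of the step size; the LQR solution adapts
#: through the dynamics).  Chosen once so a noiseless 0.3-radius reach covers
#: >= 95 % of the distance within one second at both shipped step sizes.
DEFAULT_W_V = 0.06
DEFAULT_W_R = 0.012

#: Process-noise standard deviation per velocity component, expressed as a
#: fraction of the peak reach speed, accumulated over one velocity time
#: constant (diffusion scaling keeps behaviour comparable across step sizes).
SPEED_NOISE_FRACTION = 0.05


@dataclass(frozen=True)
class LinearDynamics:
    """Discrete kinematic model: position/velocity with control on velocity."""

    A: np.ndarray
    B: np.ndarray
    W: np.ndarray
    delta: float
    alpha_decay: float

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        expected = np.array([
            [1, 0, self.delta, 0],
            [0, 1, 0, self.delta],
            [0, 0, self.alpha_decay, 0],
            [0, 0, 0, self.alpha_decay],
        ])
        if not np.allclose(A, expected):
            raise ValueError("A does not have the position/velocity sparsity")
        B = np.asarray(self.B, dtype=float)
        if not np.allclose(B, np.array([[0, 0], [0, 0], [1, 0], [0, 1]], dtype=float)):
            raise ValueError("B must inject control into the velocity rows")
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W[:2], 0) or not np.allclose(W[:, :2], 0):
            raise ValueError("process noise must live in the velocity block")


@dataclass(frozen=True)
class OFCCost:
    w_v: float = DEFAULT_W_V
    w_r: float = DEFAULT_W_R

    def __post_init__(self):
        if self.w_v < 0 or self.w_r <= 0:
            raise ValueError("need w_v >= 0 and w_r > 0")


@dataclass(frozen=True)
class TaskConfig:
    n_targets: int = 8
    radius: float = 0.3
    trial_duration: float = 2.0
    order: str = "counter_clockwise"  # or "uniform_random"
    n_trials: int = 8
    seed: int | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.order not in ("counter_clockwise", "uniform_random"):
            raise ValueError(f"unknown target order {self.order!r}")

    def steps_per_trial(self, delta: float) -> int:
        n = self.trial_duration / delta
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration must be an integer multiple of delta")
        return int(round(n))

    def target_angles(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.n_targets) / self.n_targets

    def target_sequence(self, n_trials: int, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.order == "counter_clockwise":
            return np.arange(n_trials) % self.n_targets
        if rng is None:
            rng = np.random.default_rng(self.seed)
        return rng.integers(0, self.n_targets, size=n_trials)


@dataclass
class SessionKinematics:
    """Time-indexed kinematics of one task session."""

    states: np.ndarray      # (T, 4) [dx, dy, vx, vy]
    controls: np.ndarray    # (T, 2)
    targets: np.ndarray     # (T, 2) active target position (center during return)
    trial_index: np.ndarray  # (T,)
    target_ids: np.ndarray  # (n_trials,) peripheral target id per trial
    delta: float

    @property
    def velocities(self) -> np.ndarray:
        return self.states[:, 2:]

    @property
    def positions(self) -> np.ndarray:
        return self.states[:, :2]

    def regressors(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.states)), self.velocities])

    def to_frame(self):
        import pandas as pd

        T = len(self.states)
        return pd.DataFrame({
            "step": np.arange(T), "time": np.arange(T) * self.delta,
            "trial": self.trial_index,
            "target_x": self.targets[:, 0], "target_y": self.targets[:, 1],
            "d_x": self.states[:, 0], "d_y": self.states[:, 1],
            "v_x": self.states[:, 2], "v_y": self.states[:, 3],
            "u_x": self.controls[:, 0], "u_y": self.controls[:, 1],
        })


def default_dynamics(delta: float, noise_std: float | None = None) -> LinearDynamics:
    """Kinematic model at step ``delta`` with the default time constant.

    ``noise_std`` is the per-step velocity noise SD; if omitted it is derived
    from the peak reach speed of the default task (see
    :func:`calibrated_noise_std`).
    """
    alpha = float(np.exp(-delta / VELOCITY_TAU))
    A = np.array([
        [1, 0, delta, 0],
        [0, 1, 0, delta],
        [0, 0, alpha, 0],
        [0, 0, 0, alpha],
    ])
    B = np.array([[0, 0], [0, 0], [1, 0], [0, 1]], dtype=float)
    if noise_std is None:
        noise_std = calibrated_noise_std(delta)
    W = np.zeros((4, 4))
    W[2, 2] = W[3, 3] = noise_std**2
    return LinearDynamics(A=A, B=B, W=W, delta=delta, alpha_decay=alpha)


def default_cost() -> OFCCost:
    return OFCCost()


def lqg_gain(dyn: LinearDynamics, cost: OFCCost, tol: float = 1e-12,
             max_iter: int = 100_000) -> np.ndarray:
    """Infinite-horizon LQR gain by value-iterating the discrete Riccati map."""
    A, B = dyn.A, dyn.B
    Qc = np.diag([1.0, 1.0, cost.w_v, cost.w_v])
    R = cost.w_r * np.eye(2)
    P = Qc.copy()
    for _ in range(max_iter):
        BtP = B.T @ P
        L = np.linalg.solve(R + BtP @ B, BtP @ A)
        P_next = Qc + A.T @ P @ (A - B @ L)
        P_next = 0.5 * (P_next + P_next.T)
        if np.max(np.abs(P_next - P)) < tol:
            P = P_next
            break
        P = P_next
    else:
        raise np.linalg.LinAlgError("Riccati value iteration did not converge")
    BtP = B.T @ P
    L = np.linalg.solve(R + BtP @ B, BtP @ A)
    if np.max(np.abs(np.linalg.eigvals(A - B @ L))) >= 1.0:
        raise np.linalg.LinAlgError("closed loop A - B L is not stable")
    return L


def ofc_step(x, target, L, dyn: LinearDynamics, rng: np.random.Generator | None = None):
    """One closed-form OFC step toward ``target`` (2-vector position)."""
    x = np.asarray(x, dtype=float)
    x_star = np.concatenate([np.asarray(target, dtype=float), [0.0, 0.0]])
    u = -L @ (x - x_star)
    x_next = dyn.A @ x + dyn.B @ u
    if rng is not None:
        std = np.sqrt(np.diag(dyn.W)[2:])
        if np.any(std > 0):
            x_next[2:] += rng.normal(size=2) * std
    return x_next, u


def _target_positions(task: TaskConfig) -> np.ndarray:
    ang = task.target_angles()
    return task.radius * np.column_stack([np.cos(ang), np.sin(ang)])


def peak_reach_speed(delta: float, cost: OFCCost | None = None,
                     radius: float = 0.3) -> float:
    """Peak speed of one noiseless center-out reach (task speed scale)."""
    cost = cost or default_cost()
    alpha = float(np.exp(-delta / VELOCITY_TAU))
    A = np.array([[1, 0, delta, 0], [0, 1, 0, delta],
                  [0, 0, alpha, 0], [0, 0, 0, alpha]])
    B = np.array([[0, 0], [0, 0], [1, 0], [0, 1]], dtype=float)
    dyn = LinearDynamics(A=A, B=B, W=np.zeros((4, 4)), delta=delta, alpha_decay=alpha)
    L = lqg_gain(dyn, cost)
    x = np.zeros(4)
    target = np.array([radius, 0.0])
    peak = 0.0
    for _ in range(int(round(2.0 / delta))):
        x, _ = ofc_step(x, target, L, dyn)
        peak = max(peak, float(np.hypot(x[2], x[3])))
    return peak


def calibrated_noise_std(delta: float) -> float:
    """Velocity noise SD per step giving ~5 % speed jitter per time constant."""
    v_peak = peak_reach_speed(delta)
    return SPEED_NOISE_FRACTION * v_peak * np.sqrt(delta / VELOCITY_TAU)


def generate_session(task: TaskConfig, dyn: LinearDynamics, cost: OFCCost,
                     rng: np.random.Generator) -> SessionKinematics:
    """Simulate intended kinematics for a whole session (no decoder in loop)."""
    L = lqg_gain(dyn, cost)
    steps = task.steps_per_trial(dyn.delta)
    half = steps // 2
    targets_xy = _target_positions(task)
    order_rng = rng.spawn(1)[0] if task.order == "uniform_random" else None
    ids = task.target_sequence(task.n_trials, order_rng)

    T = task.n_trials * steps
    states = np.empty((T, 4))
    controls = np.empty((T, 2))
    targets = np.empty((T, 2))
    trial_index = np.empty(T, dtype=int)
    x = np.zeros(4)
    t = 0
    center = np.zeros(2)
    for trial in range(task.n_trials):
        peripheral = targets_xy[ids[trial]]
        for k in range(steps):
            goal = peripheral if k < half else center
            x, u = ofc_step(x, goal, L, dyn, rng)
            states[t] = x
            controls[t] = u
            targets[t] = goal
            trial_index[t] = trial
            t += 1
    return SessionKinematics(states=states, controls=controls, targets=targets,
                             trial_index=trial_index, target_ids=ids, delta=dyn.delta)


def closed_loop_session(task: TaskConfig, dyn: LinearDynamics, cost: OFCCost,
                        ensemble, decoder, rng: np.random.Generator,
                        adapt=None):
    """Closed-loop session: the OFC subject acts on the *decoded* cursor state.

    ``decoder`` is a callable ``decoder(observation_row, intended_velocity)``
    protocol object from :mod:`ratecal.decoders` (see
    ``KinematicDecoderSession``); ``adapt`` optionally carries an adaptive
    filter consuming (intended velocity, observation) pairs each step.

    Returns ``(SessionKinematics of intended states, decoded states array)``.
    The heavy Monte-Carlo paths use the vectorized kernels in
    :mod:`ratecal.experiments` instead; this reference implementation is kept
    simple and is what those kernels are validated against.
    """
    from .models import LOG_RATE_CAP, GaussianChannelModel

    L = lqg_gain(dyn, cost)
    steps = task.steps_per_trial(dyn.delta)
    half = steps // 2
    targets_xy = _target_positions(task)
    order_rng = rng.spawn(1)[0] if task.order == "uniform_random" else None
    ids = task.target_sequence(task.n_trials, order_rng)

    gaussian = isinstance(ensemble[0], GaussianChannelModel)
    T = task.n_trials * steps
    states = np.empty((T, 4))
    controls = np.empty((T, 2))
    targets = np.empty((T, 2))
    trial_index = np.empty(T, dtype=int)
    decoded = np.empty((T, 4))
    v_int = np.zeros(2)
    x_dec = np.zeros(4)
    std = np.sqrt(np.diag(dyn.W)[2:])
    t = 0
    center = np.zeros(2)
    for trial in range(task.n_trials):
        peripheral = targets_xy[ids[trial]]
        for k in range(steps):
            goal = peripheral if k < half else center
            x_star = np.concatenate([goal, [0.0, 0.0]])
            u = -L @ (x_dec - x_star)
            v_int = dyn.alpha_decay * v_int + u + rng.normal(size=2) * std
            # neural activity encodes the intended velocity
            if gaussian:
                obs = np.array([
                    m.psi() @ np.concatenate([[1.0], v_int])
                    + rng.normal() * np.sqrt(m.Z) for m in ensemble
                ])
            else:
                lam = np.array([
                    np.exp(min(m.phi() @ np.concatenate([[1.0], v_int]), LOG_RATE_CAP))
                    for m in ensemble
                ])
                obs = (rng.random(len(ensemble)) < np.minimum(lam * ensemble[0].delta, 1.0)).astype(float)
            if adapt is not None:
                adapt.partial_fit(v_int[None, :], obs[None, :])
            x_dec = decoder.step(obs)
            states[t] = np.concatenate([x_dec[:2], v_int])
            controls[t] = u
            targets[t] = goal
            trial_index[t] = trial
            decoded[t] = x_dec
            t += 1
    kin = SessionKinematics(states=states, controls=controls, targets=targets,
                            trial_index=trial_index, target_ids=ids, delta=dyn.delta)
    return kin, decoded
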