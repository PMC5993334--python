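"""Recursive Bayesian estimators of encoding-model parameters.

Both filters place a random-walk prior with covariance ``rate * I`` on the
unknown (but essentially fixed) encoding parameters and assimilate one
observation per time bin:

* adaptive Kalman filter (continuous channel)::

      psi_pred = psi;  S_pred = S + s I
      S_upd    = (S_pred^-1 + v~ v~' / Z)^-1
      psi_upd  = psi_pred + S_upd v~ (y - v~' psi_pred) / Z

* adaptive point-process filter (spike channel, Laplace-Gaussian posterior)::

      phi_pred = phi;  Q_pred = Q + r I
      Q_upd    = (Q_pred^-1 + v~ v~' lambda(phi_pred) delta)^-1
      phi_upd  = phi_pred + Q_upd v~ (N - lambda(phi_pred) delta)

Channels are conditionally independent given the encoded state, so each
channel runs its own small filter; :func:`run_adaptation` streams a whole
session through an ensemble of channels.  The estimator classes
(:class:`AdaptiveKalmanFilter`, :class:`AdaptivePointProcessFilter`) wrap the
same recursions in a sklearn-style ``fit``/``partial_fit`` interface.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .models import LOG_RATE_CAP, GaussianChannelModel

__all__ = [
    "FilterState",
    "NoiseEstimatorState",
    "AdaptationTrace",
    "kf_update",
    "ppf_update",
    "covariance_match_Z",
    "run_adaptation",
    "AdaptiveKalmanFilter",
    "AdaptivePointProcessFilter",
]

_SYM_TOL = 1e-10


@dataclass
class FilterState:
    """Posterior mean and covariance of one channel's parameter estimate."""

    mean: np.ndarray
    cov: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.size
        if self.cov.shape != (n, n):
            raise ValueError("cov shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=_SYM_TOL):
            raise ValueError("cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -_SYM_TOL):
            raise ValueError("cov must be positive semi-definite")


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _information_update(cov_pred: np.ndarray, v_tilde: np.ndarray, weight: float) -> np.ndarray:
    """Covariance update ``(P^-1 + w v v')^-1`` via a symmetric rank-one
    downdate (Sherman-Morrison) with explicit re-symmetrization.

    Algebraically identical to the information form but SPD-safe, and well
    defined for a frozen filter (zero prediction covariance).  The test suite
    asserts equality with the explicit information-form solve.
    """
    Pv = cov_pred @ v_tilde
    denom = 1.0 + weight * (v_tilde @ Pv)
    if not np.isfinite(denom) or denom <= 0:
        raise np.linalg.LinAlgError(
            "singular or indefinite prediction covariance in filter update"
        )
    cov = cov_pred - np.outer(Pv, Pv) * (weight / denom)
    return _symmetrize(cov)


def kf_update(state: FilterState, s: float, y: float, v_tilde, Z: float) -> FilterState:
    """One adaptive-KF step at learning rate ``s`` for a known noise variance."""
    if s < 0:
        raise ValueError("learning rate s must be >= 0")
    if not (Z > 0):
        raise ValueError("noise variance Z must be > 0")
    v_tilde = np.asarray(v_tilde, dtype=float).ravel()
    mean_pred = state.mean
    cov_pred = state.cov + s * np.eye(state.mean.size)
    cov_upd = _information_update(cov_pred, v_tilde, 1.0 / Z)
    innovation = y - v_tilde @ mean_pred
    mean_upd = mean_pred + cov_upd @ v_tilde * (innovation / Z)
    return FilterState(mean=mean_upd, cov=cov_upd, t=state.t + 1)


def ppf_update(state: FilterState, r: float, N: int, v_tilde, delta: float) -> FilterState:
    """One adaptive-PPF step at learning rate ``r`` (Laplace approximation)."""
    if r < 0:
        raise ValueError("learning rate r must be >= 0")
    if N not in (0, 1):
        raise ValueError("spike indicator N must be 0 or 1")
    if not (delta > 0):
        raise ValueError("delta must be > 0")
    v_tilde = np.asarray(v_tilde, dtype=float).ravel()
    mean_pred = state.mean
    cov_pred = state.cov + r * np.eye(state.mean.size)
    lam = np.exp(min(v_tilde @ mean_pred, LOG_RATE_CAP))
    if not np.isfinite(lam):  # pragma: no cover - capped upstream
        raise FloatingPointError("non-finite conditional intensity in ppf_update")
    cov_upd = _information_update(cov_pred, v_tilde, lam * delta)
    mean_upd = mean_pred + cov_upd @ v_tilde * (N - lam * delta)
    return FilterState(mean=mean_upd, cov=cov_upd, t=state.t + 1)


@dataclass
class NoiseEstimatorState:
    """Covariance-matching estimator of the observation noise variance.

    Over a sliding window of ``L`` innovations ``q_j = y_j - v~' psi_{j|j-1}``
    and prediction terms ``v~' S_{j|j-1} v~``, the variance estimate is::

        Z = 1/(L-1) sum (q_j - q_bar)^2  -  1/L sum v~_j' S_{j|j-1} v~_j

    floored at ``z_floor`` to stay positive.  The estimate is refreshed right
    after the filter's prediction step and used in that step's update.
    """

    window_length: int = 200
    z_floor: float = 1e-6
    residuals: deque = field(default_factory=deque)
    pred_terms: deque = field(default_factory=deque)
    current_Z: float = 1.0

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not (self.z_floor > 0):
            raise ValueError("z_floor must be > 0")
        self.residuals = deque(self.residuals, maxlen=self.window_length)
        self.pred_terms = deque(self.pred_terms, maxlen=self.window_length)


def covariance_match_Z(est: NoiseEstimatorState, new_residual: float,
                       new_pred_term: float) -> NoiseEstimatorState:
    """Push one innovation and refresh the covariance-matching estimate."""
    est.residuals.append(float(new_residual))
    est.pred_terms.append(float(new_pred_term))
    L = len(est.residuals)
    if L >= 2:
        q = np.asarray(est.residuals)
        raw = q.var(ddof=1) - float(np.mean(est.pred_terms))
        if raw <= 0:
            warnings.warn(
                "covariance-matching estimate non-positive; flooring",
                RuntimeWarning, stacklevel=2,
            )
            raw = est.z_floor
        est.current_Z = max(raw, est.z_floor)
    return est


@dataclass
class AdaptationTrace:
    """Time-indexed record of one channel's adaptation run."""

    means: np.ndarray          # (T, n) posterior means
    cov_diags: np.ndarray      # (T, n) posterior covariance diagonals
    observations: np.ndarray   # (T,)
    truth: np.ndarray | None   # (n,) true parameters if simulated
    delta: float               # seconds per step
    Z_estimates: np.ndarray | None = None  # (T,) if concurrently estimated

    def errors(self) -> np.ndarray:
        if self.truth is None:
            raise ValueError("trace has no ground truth")
        return self.truth[None, :] - self.means

    def to_frame(self, channel: int = 0):
        import pandas as pd

        T, n = self.means.shape
        data = {"step": np.arange(T), "time": np.arange(T) * self.delta,
                "channel": channel, "observation": self.observations}
        for j in range(n):
            data[f"mean_{j}"] = self.means[:, j]
            data[f"cov_{j}"] = self.cov_diags[:, j]
            if self.truth is not None:
                data[f"truth_{j}"] = self.truth[j]
        if self.Z_estimates is not None:
            data["Z_est"] = self.Z_estimates
        return pd.DataFrame(data)


def run_adaptation(models, states, session, rate, *, observations=None,
                   rng=None, concurrent_Z=False, window_L=200,
                   z_init=None, delta=None) -> list[AdaptationTrace]:
    """Stream a session through an ensemble of per-channel filters.

    Parameters
    ----------
    models : list of channel models (all Gaussian or all point-process).
    states : list of FilterState, one per channel (consumed, not mutated).
    session : (T, d) array of encoded states (velocities).
    rate : learning rate (s for KF, r for PPF).
    observations : optional (T, C) array; if omitted, observations are
        simulated from the true models using ``rng``.
    concurrent_Z : estimate the noise variance by covariance matching
        (Gaussian channels only), starting from ``z_init``.
    """
    session = np.asarray(session, dtype=float)
    if session.ndim != 2 or len(session) == 0:
        raise ValueError("session must be a non-empty (T, d) array")
    if len(models) != len(states):
        raise ValueError("one initial state per channel is required")
    T = len(session)
    V = np.column_stack([np.ones(T), session])

    gaussian = isinstance(models[0], GaussianChannelModel)
    if observations is None:
        if rng is None:
            raise ValueError("need rng to simulate observations")
        if gaussian:
            psi = np.stack([m.psi() for m in models])
            Zs = np.array([m.Z for m in models])
            observations = V @ psi.T + rng.normal(size=(T, len(models))) * np.sqrt(Zs)
        else:
            phi = np.stack([m.phi() for m in models])
            lam = np.exp(np.minimum(V @ phi.T, LOG_RATE_CAP))
            p = np.minimum(lam * models[0].delta, 1.0)
            observations = (rng.random(size=(T, len(models))) < p).astype(float)
    observations = np.asarray(observations, dtype=float)
    if observations.shape != (T, len(models)):
        raise ValueError("observations shape must be (T, n_channels)")

    traces = []
    for c, (model, state0) in enumerate(zip(models, states)):
        st = FilterState(mean=state0.mean.copy(), cov=state0.cov.copy(), t=state0.t)
        n = st.mean.size
        means = np.empty((T, n))
        cov_diags = np.empty((T, n))
        z_tr = np.empty(T) if (concurrent_Z and gaussian) else None
        est = None
        if concurrent_Z and gaussian:
            z0 = float(z_init if z_init is not None else model.Z)
            est = NoiseEstimatorState(window_length=window_L,
                                      z_floor=1e-6 * z0, current_Z=z0)
        for t in range(T):
            v_tilde = V[t]
            y = observations[t, c]
            if gaussian:
                if est is not None:
                    cov_pred = st.cov + rate * np.eye(n)
                    q = y - v_tilde @ st.mean
                    covariance_match_Z(est, q, v_tilde @ cov_pred @ v_tilde)
                    Z_use = est.current_Z
                    z_tr[t] = Z_use
                else:
                    Z_use = model.Z
                st = kf_update(st, rate, y, v_tilde, Z_use)
            else:
                st = ppf_update(st, rate, int(y), v_tilde, model.delta)
            means[t] = st.mean
            cov_diags[t] = np.diag(st.cov)
        truth = model.psi() if gaussian else model.phi()
        step_s = delta if delta is not None else (0.1 if gaussian else models[0].delta)
        traces.append(AdaptationTrace(
            means=means, cov_diags=cov_diags,
            observations=observations[:, c].copy(), truth=truth,
            delta=step_s, Z_estimates=z_tr))
    return traces


class _BaseAdaptiveFilter:
    """Shared sklearn-style plumbing for the two adaptive filters."""

    _param_names: tuple = ()

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _validate_Xy(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (T, d) encoded states")
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        return np.column_stack([np.ones(len(X)), X]), y


class AdaptiveKalmanFilter(_BaseAdaptiveFilter):
    """Online estimator of linear-Gaussian encoding parameters.

    Parameters
    ----------
    learning_rate : float
        Random-walk prior variance per step (the calibrated quantity).
    Z : float or (C,) array or None
        Observation noise variance(s).  ``None`` activates concurrent
        covariance-matching estimation started from ``z_init``.
    init_cov_scale : float
        Diagonal of the initial posterior covariance (dB^2).
    window_L : int
        Covariance-matching window length.

    Attributes
    ----------
    coef_ : (C, 1+d) posterior means after ``fit``.
    cov_ : (C, 1+d, 1+d) posterior covariances.
    Z_ : (C,) final noise-variance estimates (when estimated).
    """

    _param_names = ("learning_rate", "Z", "init_cov_scale", "window_L", "z_init")

    def __init__(self, learning_rate=1e-4, Z=None, init_cov_scale=1.0,
                 window_L=200, z_init=None):
        self.learning_rate = learning_rate
        self.Z = Z
        self.init_cov_scale = init_cov_scale
        self.window_L = window_L
        self.z_init = z_init

    def _init_state(self, n_channels, n_params, coef_init=None):
        coef = (np.zeros((n_channels, n_params)) if coef_init is None
                else np.array(coef_init, dtype=float))
        self.coef_ = coef
        self.cov_ = np.repeat(self.init_cov_scale * np.eye(n_params)[None], n_channels, axis=0)
        self.n_steps_ = 0
        if self.Z is None:
            z0 = float(self.z_init if self.z_init is not None else 1.0)
            self._noise_ests = [
                NoiseEstimatorState(window_length=self.window_L,
                                    z_floor=1e-6 * z0, current_Z=z0)
                for _ in range(n_channels)
            ]
        else:
            self._noise_ests = None

    def partial_fit(self, X, y, coef_init=None):
        V, y = self._validate_Xy(X, y)
        if not hasattr(self, "coef_"):
            self._init_state(y.shape[1], V.shape[1], coef_init)
        Zs = None if self.Z is None else np.broadcast_to(
            np.atleast_1d(np.asarray(self.Z, dtype=float)), (y.shape[1],))
        s = self.learning_rate
        for t in range(len(V)):
            v_tilde = V[t]
            for c in range(y.shape[1]):
                st = FilterState(self.coef_[c], self.cov_[c], self.n_steps_)
                if self._noise_ests is not None:
                    est = self._noise_ests[c]
                    cov_pred = st.cov + s * np.eye(st.mean.size)
                    q = y[t, c] - v_tilde @ st.mean
                    covariance_match_Z(est, q, v_tilde @ cov_pred @ v_tilde)
                    Z_use = est.current_Z
                else:
                    Z_use = Zs[c]
                st = kf_update(st, s, y[t, c], v_tilde, Z_use)
                self.coef_[c] = st.mean
                self.cov_[c] = st.cov
            self.n_steps_ += 1
        if self._noise_ests is not None:
            self.Z_ = np.array([e.current_Z for e in self._noise_ests])
        return self

    def fit(self, X, y, coef_init=None):
        for attr in ("coef_", "cov_", "n_steps_"):
            if hasattr(self, attr):
                delattr(self, attr)
        return self.partial_fit(X, y, coef_init=coef_init)

    def predict(self, X):
        """Expected observations given the current parameter estimates."""
        X = np.asarray(X, dtype=float)
        V = np.column_stack([np.ones(len(X)), X])
        return V @ self.coef_.T


class AdaptivePointProcessFilter(_BaseAdaptiveFilter):
    """Online estimator of log-linear point-process encoding parameters.

    Same interface as :class:`AdaptiveKalmanFilter`; ``y`` holds binary spike
    indicators, one column per neuron, in bins of width ``delta`` seconds.
    """

    _param_names = ("learning_rate", "delta", "init_cov_scale")

    def __init__(self, learning_rate=1e-7, delta=0.001, init_cov_scale=1e-2):
        self.learning_rate = learning_rate
        self.delta = delta
        self.init_cov_scale = init_cov_scale

    def partial_fit(self, X, y, coef_init=None):
        V, y = self._validate_Xy(X, y)
        if not hasattr(self, "coef_"):
            self.coef_ = (np.zeros((y.shape[1], V.shape[1])) if coef_init is None
                          else np.array(coef_init, dtype=float))
            self.cov_ = np.repeat(self.init_cov_scale * np.eye(V.shape[1])[None],
                                  y.shape[1], axis=0)
            self.n_steps_ = 0
        for t in range(len(V)):
            for c in range(y.shape[1]):
                st = FilterState(self.coef_[c], self.cov_[c], self.n_steps_)
                st = ppf_update(st, self.learning_rate, int(y[t, c]), V[t], self.delta)
                self.coef_[c] = st.mean
                self.cov_[c] = st.cov
            self.n_steps_ += 1
        return self

    def fit(self, X, y, coef_init=None):
        for attr in ("coef_", "cov_", "n_steps_"):
            if hasattr(self, attr):
                delattr(self, attr)
        return self.partial_fit(X, y, coef_init=coef_init)

    def predict_rate(self, X):
        """Conditional intensity (Hz) per neuron at the current estimates."""
        X = np.asarray(X, dtype=float)
        V = np.column_stack([np.ones(len(X)), X])
        return np.exp(np.minimum(V @ self.coef_.T, LOG_RATE_CAP))
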