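"""Velocity decoders — the second decoder that turns neural observations into
cursor kinematics given the current encoding-parameter estimates.

Both decoders share the kinematic prior (the task dynamics with ``u = 0``):
position integrates the decoded velocity (dead reckoning) and the observations
couple to the state only through the velocity components, because the encoding
models depend on velocity alone.

* KF decoder: each continuous channel contributes a scalar linear observation
  ``y = xi + eta' v + noise``; channels are conditionally independent, so the
  update assimilates them sequentially (exact for linear-Gaussian models).
* PPF decoder: each neuron contributes a Bernoulli observation with log-linear
  intensity; the Laplace-Gaussian update adds ``alpha alpha' lambda delta`` to
  the information and ``alpha (N - lambda delta)`` to the score, evaluated at
  the prediction mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import LOG_RATE_CAP
from .ofc import LinearDynamics

__all__ = [
    "KinematicDecoderState",
    "kf_decode_step",
    "ppf_decode_step",
    "KinematicDecoderSession",
]


@dataclass
class KinematicDecoderState:
    """Decoded kinematic state [d_x, d_y, v_x, v_y] with its covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(4)
        self.cov = np.asarray(self.cov, dtype=float).reshape(4, 4)


def _predict(state: KinematicDecoderState, prior: LinearDynamics):
    mean = prior.A @ state.mean
    cov = prior.A @ state.cov @ prior.A.T + prior.W
    return mean, 0.5 * (cov + cov.T)


def kf_decode_step(state: KinematicDecoderState, observations, params, Z,
                   prior: LinearDynamics) -> KinematicDecoderState:
    """One predict/update cycle of the velocity Kalman decoder.

    ``observations`` is the per-channel feature vector y_t, ``params`` the
    (C, 3) array of [xi, eta_x, eta_y] estimates, ``Z`` the per-channel noise
    variances.
    """
    observations = np.atleast_1d(np.asarray(observations, dtype=float))
    params = np.atleast_2d(np.asarray(params, dtype=float))
    Z = np.broadcast_to(np.atleast_1d(np.asarray(Z, dtype=float)), observations.shape)
    mean, cov = _predict(state, prior)
    for c in range(len(observations)):
        h = np.array([0.0, 0.0, params[c, 1], params[c, 2]])
        Ph = cov @ h
        denom = Z[c] + h @ Ph
        if denom <= 0:
            raise np.linalg.LinAlgError("singular innovation covariance")
        gain = Ph / denom
        mean = mean + gain * (observations[c] - params[c, 0] - h @ mean)
        cov = cov - np.outer(gain, Ph)
        cov = 0.5 * (cov + cov.T)
    return KinematicDecoderState(mean=mean, cov=cov)


def ppf_decode_step(state: KinematicDecoderState, spikes, params, delta: float,
                    prior: LinearDynamics) -> KinematicDecoderState:
    """One predict/update cycle of the velocity point-process decoder."""
    spikes = np.atleast_1d(np.asarray(spikes, dtype=float))
    params = np.atleast_2d(np.asarray(params, dtype=float))
    mean, cov = _predict(state, prior)
    for c in range(len(spikes)):
        g = np.array([0.0, 0.0, params[c, 1], params[c, 2]])
        lam = np.exp(min(params[c, 0] + g @ mean, LOG_RATE_CAP))
        w = lam * delta
        Pg = cov @ g
        denom = 1.0 + w * (g @ Pg)
        cov_new = cov - np.outer(Pg, Pg) * (w / denom)
        cov = 0.5 * (cov_new + cov_new.T)
        mean = mean + (cov @ g) * (spikes[c] - w)
    return KinematicDecoderState(mean=mean, cov=cov)


class KinematicDecoderSession:
    """Stateful decoder wrapper used by the closed-loop simulator.

    Holds the running :class:`KinematicDecoderState` and the (possibly frozen
    or concurrently adapted) encoding-parameter estimates.
    """

    def __init__(self, kind: str, params, prior: LinearDynamics, Z=None,
                 delta: float | None = None, init_cov: float = 1e-2):
        if kind not in ("gaussian", "point_process"):
            raise ValueError(f"unknown decoder kind {kind!r}")
        self.kind = kind
        self.params = np.atleast_2d(np.asarray(params, dtype=float)).copy()
        self.prior = prior
        self.Z = Z
        self.delta = delta if delta is not None else prior.delta
        self.state = KinematicDecoderState(np.zeros(4), init_cov * np.eye(4))

    def step(self, observations) -> np.ndarray:
        if self.kind == "gaussian":
            self.state = kf_decode_step(self.state, observations, self.params,
                                        self.Z, self.prior)
        else:
            self.state = ppf_decode_step(self.state, observations, self.params,
                                         self.delta, self.prior)
        return self.state.mean.copy()
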