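"""Neural encoding models and stochastic observation generators.

Two observation families are supported:

* :class:`GaussianChannelModel` — a continuous feature (e.g. the log-power of an
  LFP/ECoG band) that depends linearly on the encoded 2-D velocity, observed
  with additive white Gaussian noise:  ``y_t = psi' v_tilde_t + z_t`` with
  ``psi = [xi, eta_x, eta_y]`` and ``Var[z_t] = Z``.
* :class:`PointProcessChannelModel` — a binary spike train per time bin, with a
  log-linear conditional intensity ``lambda(v) = exp(beta + alpha' v)`` and at
  most one spike per bin of width ``delta`` (spike probability
  ``min(lambda * delta, 1)``).

The log-linear intensity is equivalent to a modified cosine-tuning model,
``lambda(v) = exp(beta + |alpha| |v| cos(theta_v - theta_pd))``, which is how
ensembles are parameterised (baseline rate, maximum rate, preferred direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GaussianChannelModel",
    "PointProcessChannelModel",
    "GaussianEnsembleSpec",
    "PointProcessEnsembleSpec",
    "build_regressor",
    "gaussian_observe",
    "firing_rate",
    "firing_rate_cosine",
    "tuning_from_rates",
    "sample_spike",
    "sample_channel_ensemble",
    "ensemble_to_frame",
    "ensemble_from_frame",
]

#: Cap on the log-rate exponent; guards against overflow when the intensity is
#: evaluated at transiently bad parameter estimates.
LOG_RATE_CAP = 50.0


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x


@dataclass(frozen=True)
class GaussianChannelModel:
    """Linear-Gaussian encoding of velocity in one continuous channel.

    Parameters
    ----------
    xi : float
        Baseline log-power (dB).
    eta : (2,) array
        Velocity tuning coefficients (dB per velocity unit).
    Z : float
        Observation noise variance (dB^2), strictly positive.
    """

    xi: float
    eta: np.ndarray
    Z: float

    def __post_init__(self):
        object.__setattr__(self, "eta", _check_finite(self.eta, "eta").reshape(2))
        if not np.isfinite(self.xi):
            raise ValueError("xi must be finite")
        if not (self.Z > 0):
            raise ValueError(f"noise variance Z must be > 0, got {self.Z}")

    def psi(self) -> np.ndarray:
        """Parameter vector ``[xi, eta_x, eta_y]``."""
        return np.concatenate([[self.xi], self.eta])

    @property
    def modulation_depth(self) -> float:
        return float(np.linalg.norm(self.eta))

    @property
    def preferred_direction(self) -> float:
        return float(np.arctan2(self.eta[1], self.eta[0]) % (2 * np.pi))


@dataclass(frozen=True)
class PointProcessChannelModel:
    """Log-linear point-process (GLM) encoding of velocity in one neuron.

    ``beta`` is the log baseline rate (log Hz), ``alpha`` the 2-vector of
    velocity coefficients, and ``delta`` the bin width in seconds.  The
    one-spike-per-bin regime requires ``exp(beta) * delta <= 1``.
    """

    beta: float
    alpha: np.ndarray
    delta: float

    def __post_init__(self):
        object.__setattr__(self, "alpha", _check_finite(self.alpha, "alpha").reshape(2))
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not (self.delta > 0):
            raise ValueError(f"bin width delta must be > 0, got {self.delta}")
        if np.exp(self.beta) * self.delta > 1.0 + 1e-12:
            raise ValueError(
                "exp(beta) * delta > 1: baseline rate violates the "
                "one-spike-per-bin regime"
            )

    def phi(self) -> np.ndarray:
        """Parameter vector ``[beta, alpha_x, alpha_y]``."""
        return np.concatenate([[self.beta], self.alpha])

    @property
    def modulation_depth(self) -> float:
        return float(np.linalg.norm(self.alpha))

    @property
    def preferred_direction(self) -> float:
        return float(np.arctan2(self.alpha[1], self.alpha[0]) % (2 * np.pi))


def build_regressor(v) -> np.ndarray:
    """Return the augmented regressor ``v_tilde = [1, v']'``."""
    v = _check_finite(v, "encoded state v").ravel()
    return np.concatenate([[1.0], v])


def gaussian_observe(model: GaussianChannelModel, v_tilde, rng: np.random.Generator) -> float:
    """Draw one observation ``psi' v_tilde + z`` with ``z ~ N(0, Z)``."""
    v_tilde = np.asarray(v_tilde, dtype=float)
    return float(model.psi() @ v_tilde + rng.normal(0.0, np.sqrt(model.Z)))


def firing_rate(model: PointProcessChannelModel, v) -> float:
    """Instantaneous rate ``exp(beta + alpha' v)`` in Hz (exponent capped)."""
    v = _check_finite(v, "velocity v").reshape(2)
    return float(np.exp(min(model.beta + model.alpha @ v, LOG_RATE_CAP)))


def firing_rate_cosine(model: PointProcessChannelModel, v) -> float:
    """Same rate via the cosine-tuning form ``exp(beta + |a||v| cos(dtheta))``."""
    v = _check_finite(v, "velocity v").reshape(2)
    speed = np.linalg.norm(v)
    if speed == 0.0:
        return float(np.exp(min(model.beta, LOG_RATE_CAP)))
    theta_v = np.arctan2(v[1], v[0])
    expo = model.beta + model.modulation_depth * speed * np.cos(
        theta_v - model.preferred_direction
    )
    return float(np.exp(min(expo, LOG_RATE_CAP)))


def tuning_from_rates(
    base_rate: float, max_rate: float, preferred_dir: float, v_max: float, delta: float = 0.001
) -> PointProcessChannelModel:
    """Build a point-process model from its rate description.

    The baseline rate is attained at rest and the maximum rate when moving at
    speed ``v_max`` along the preferred direction, so ``beta = ln(base_rate)``
    and ``|alpha| = ln(max_rate / base_rate) / v_max``.
    """
    if not (0 < base_rate < max_rate):
        raise ValueError("need 0 < base_rate < max_rate")
    if not (v_max > 0):
        raise ValueError("v_max must be > 0")
    depth = np.log(max_rate / base_rate) / v_max
    alpha = depth * np.array([np.cos(preferred_dir), np.sin(preferred_dir)])
    return PointProcessChannelModel(beta=float(np.log(base_rate)), alpha=alpha, delta=delta)


def sample_spike(model: PointProcessChannelModel, v, rng: np.random.Generator) -> int:
    """Draw a binary spike indicator with probability ``min(lambda*delta, 1)``."""
    p = min(firing_rate(model, v) * model.delta, 1.0)
    return int(rng.random() < p)


@dataclass(frozen=True)
class GaussianEnsembleSpec:
    """Uniform sampling ranges for a continuous-feature channel ensemble."""

    xi_range: tuple = (1.0, 6.0)
    mod_depth_range: tuple = (7.0, 10.0)
    preferred_dir_range: tuple = (0.0, 2 * np.pi)
    Z_range: tuple = (320.0, 380.0)


@dataclass(frozen=True)
class PointProcessEnsembleSpec:
    """Uniform sampling ranges for a spiking-neuron ensemble."""

    base_rate_range: tuple = (4.0, 10.0)
    max_rate_range: tuple = (40.0, 80.0)
    preferred_dir_range: tuple = (0.0, 2 * np.pi)
    delta: float = 0.001
    v_max: float = 1.0


def _uniform(rng, lo_hi):
    lo, hi = lo_hi
    if hi < lo:
        raise ValueError(f"empty range {lo_hi}")
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def sample_channel_ensemble(spec, n_channels: int, rng: np.random.Generator) -> list:
    """Draw ``n_channels`` independent channel models from ``spec``.

    Each channel gets its own jumpahead substream spawned from ``rng`` so that
    ensembles are bit-reproducible and insensitive to sampling order.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    streams = rng.spawn(n_channels)
    out = []
    for sub in streams:
        if isinstance(spec, GaussianEnsembleSpec):
            xi = _uniform(sub, spec.xi_range)
            theta = _uniform(sub, spec.preferred_dir_range)
            depth = _uniform(sub, spec.mod_depth_range)
            Z = _uniform(sub, spec.Z_range)
            eta = depth * np.array([np.cos(theta), np.sin(theta)])
            out.append(GaussianChannelModel(xi=xi, eta=eta, Z=Z))
        elif isinstance(spec, PointProcessEnsembleSpec):
            base = _uniform(sub, spec.base_rate_range)
            mx = _uniform(sub, spec.max_rate_range)
            theta = _uniform(sub, spec.preferred_dir_range)
            out.append(tuning_from_rates(base, mx, theta, spec.v_max, spec.delta))
        else:
            raise TypeError(f"unknown ensemble spec {type(spec)!r}")
    return out


def ensemble_to_frame(models: list) -> pd.DataFrame:
    """Serialize a channel ensemble to a flat table (one row per channel)."""
    rows = []
    for i, m in enumerate(models):
        if isinstance(m, GaussianChannelModel):
            rows.append(
                dict(channel=i, kind="gaussian", p0=m.xi, p1=m.eta[0], p2=m.eta[1],
                     noise=m.Z, delta=np.nan)
            )
        elif isinstance(m, PointProcessChannelModel):
            rows.append(
                dict(channel=i, kind="point_process", p0=m.beta, p1=m.alpha[0],
                     p2=m.alpha[1], noise=np.nan, delta=m.delta)
            )
        else:
            raise TypeError(f"unknown model {type(m)!r}")
    return pd.DataFrame(rows)


def ensemble_from_frame(frame: pd.DataFrame) -> list:
    """Inverse of :func:`ensemble_to_frame`."""
    out = []
    for _, row in frame.sort_values("channel").iterrows():
        if row["kind"] == "gaussian":
            out.append(GaussianChannelModel(xi=row["p0"],
                                            eta=np.array([row["p1"], row["p2"]]),
                                            Z=row["noise"]))
        elif row["kind"] == "point_process":
            out.append(PointProcessChannelModel(beta=row["p0"],
                                                alpha=np.array([row["p1"], row["p2"]]),
                                                delta=row["delta"]))
        else:
            raise ValueError(f"unknown model kind {row['kind']!r}")
    return out
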