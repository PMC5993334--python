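"""Analytic learning-rate calibration for adaptive Bayesian filters.

A random-walk prior with covariance ``s * I`` on the encoding parameters turns
the Kalman filter (continuous channels) or the point-process filter (spike
channels) into an adaptive estimator whose behaviour is governed entirely by
the learning rate ``s`` and the time-averaged Fisher information of the
regressors,

``H_ave = (1/T) sum_t v_tilde_t v_tilde_t' / Z``            (Gaussian)
``M_ave = (1/T) sum_t v_tilde_t v_tilde_t' lambda_t* delta``  (point process).

Writing the ascending eigendecomposition ``H_ave = U diag(h_1..h_n) U'`` and

``kappa_m = (sqrt(h_m^2 s^2 + 4 h_m s) - h_m s) / (2 h_m)``,

the steady-state parameter error covariance and the per-step decay factor of
the expected error have the closed forms

``S_+* = U diag( 1 / sqrt(h_m^2 + 4 h_m / s) ) U'``   (increasing in s)
``rho  = kappa_1 / (kappa_1 + s)``                     (decreasing in s),

which expose the trade-off between steady-state accuracy and convergence
speed.  The inverse maps select the learning rate for a bound ``V_bd`` on
``||S_+*||`` or a bound ``C_bd`` on the convergence time; both are implemented
here, together with the conservative selection over a nuisance range (unknown
noise variance, or unknown firing-rate scale for spikes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AverageInformation",
    "CalibrationResult",
    "average_information_gaussian",
    "average_information_point_process",
    "kappa",
    "steady_state_covariance",
    "convergence_factor",
    "predict_convergence_time",
    "rate_for_error_bound",
    "rate_for_time_bound",
    "conservative_rate",
    "admissible_interval",
    "LearningRateCalibrator",
]

#: Relative eigenvalue threshold below which the regressor information is
#: treated as rank deficient and calibration refuses to extrapolate.
RANK_TOL = 1e-12


@dataclass(frozen=True)
class AverageInformation:
    """Time-averaged information matrix with its ascending eigensystem."""

    matrix: np.ndarray
    eigvals: np.ndarray  # ascending, all > 0
    eigvecs: np.ndarray  # orthonormal columns, aligned with eigvals

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AverageInformation":
        matrix = np.asarray(matrix, dtype=float)
        matrix = 0.5 * (matrix + matrix.T)
        vals, vecs = np.linalg.eigh(matrix)  # eigh returns ascending order
        if vals[-1] <= 0 or vals[0] <= RANK_TOL * vals[-1]:
            raise np.linalg.LinAlgError(
                "average information is rank deficient (smallest eigenvalue "
                f"{vals[0]:.3e}); the regressor trajectory does not excite all "
                "parameter directions, so calibration is undefined"
            )
        return cls(matrix=matrix, eigvals=vals, eigvecs=vecs)

    @property
    def h1(self) -> float:
        """Smallest eigenvalue — the quantity the inverse maps depend on."""
        return float(self.eigvals[0])


@dataclass(frozen=True)
class CalibrationResult:
    """Chosen learning rate together with its analytic predictions."""

    learning_rate: float
    predicted_cov: np.ndarray
    predicted_factor: float
    predicted_convergence_time: float


def _as_regressor_matrix(v_tilde_sequence) -> np.ndarray:
    V = np.asarray(v_tilde_sequence, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[0] == 0:
        raise ValueError("regressor sequence must be non-empty")
    return V


def average_information_gaussian(v_tilde_sequence, Z: float) -> AverageInformation:
    """``(1/T) sum_t v~_t v~_t' / Z`` for a linear-Gaussian channel.

    Accepts any realized trajectory, periodic or not: only the average matters.
    """
    if not (Z > 0):
        raise ValueError("noise variance Z must be > 0")
    V = _as_regressor_matrix(v_tilde_sequence)
    return AverageInformation.from_matrix(V.T @ V / (len(V) * Z))


def average_information_point_process(v_tilde_sequence, phi_star, delta: float) -> AverageInformation:
    """``(1/T) sum_t v~_t v~_t' lambda(t|phi*) delta`` for a spiking channel."""
    if not (delta > 0):
        raise ValueError("delta must be > 0")
    V = _as_regressor_matrix(v_tilde_sequence)
    phi_star = np.asarray(phi_star, dtype=float).ravel()
    if not np.all(np.isfinite(phi_star)):
        raise ValueError("phi_star must be finite")
    lam = np.exp(np.minimum(V @ phi_star, 50.0)) * delta
    return AverageInformation.from_matrix((V * lam[:, None]).T @ V / len(V))


def kappa(h: float, s: float) -> float:
    """Unique positive root of ``h k^2 + h s k - s = 0``.

    This is the steady-state posterior variance of the scalar filtering
    Riccati map ``k -> 1 / (1/(k+s) + h)``.
    """
    if not (h > 0 and s > 0):
        raise ValueError("need h > 0 and s > 0")
    # rationalized form of (sqrt(h^2 s^2 + 4 h s) - h s) / (2 h): immune to
    # cancellation when h*s is large
    return 2.0 * s / (np.sqrt(h * h * s * s + 4.0 * h * s) + h * s)


def _ss_eigenvalue(h: np.ndarray, s: float) -> np.ndarray:
    # closed form 1/sqrt(h^2 + 4h/s); equal to (k^2 + s k)/(2 k + s)
    return 1.0 / np.sqrt(h * h + 4.0 * h / s)


def steady_state_covariance(info: AverageInformation, s: float) -> np.ndarray:
    """Steady-state parameter error covariance ``S_+*`` at learning rate ``s``."""
    if not (s > 0):
        raise ValueError("learning rate s must be > 0")
    d = _ss_eigenvalue(info.eigvals, s)
    U = info.eigvecs
    M = (U * d) @ U.T
    return 0.5 * (M + M.T)


def convergence_factor(info: AverageInformation, s: float) -> float:
    """Dominant per-step decay factor ``rho = kappa_1/(kappa_1 + s)`` in (0,1)."""
    if not (s > 0):
        raise ValueError("learning rate s must be > 0")
    k1 = kappa(info.h1, s)
    return float(k1 / (k1 + s))


def error_decay_map(info: AverageInformation, s: float) -> np.ndarray:
    """Full linear map ``U diag(kappa_m/(kappa_m+s)) U'`` driving ``E[g_t]``."""
    k = np.array([kappa(h, s) for h in info.eigvals])
    d = k / (k + s)
    U = info.eigvecs
    return (U * d) @ U.T


def predict_convergence_time(info: AverageInformation, s: float,
                             e_rest: float = 0.05, delta: float = 1.0) -> float:
    """Seconds until the expected relative error falls to ``e_rest``."""
    if not (0 < e_rest < 1):
        raise ValueError("e_rest must be in (0, 1)")
    rho = convergence_factor(info, s)
    return float(delta * np.log(e_rest) / np.log(rho))


def rate_for_error_bound(h1: float, v_bd: float) -> float:
    """Largest rate with ``||S_+*|| <= V_bd``:  ``s = 4 h1 / (1/V_bd^2 - h1^2)``.

    Feasibility requires ``1/V_bd^2 > h1^2`` (i.e. ``V_bd < 1/h1``): the
    steady-state covariance norm stays below ``1/h1`` for every finite rate.
    """
    if not (h1 > 0):
        raise ValueError("h1 must be > 0")
    if not (0 < v_bd < 1.0 / h1):
        raise ValueError(
            f"error bound V_bd={v_bd} is infeasible: need 0 < V_bd < 1/h1 = {1.0 / h1:.6g}"
        )
    return 4.0 * h1 / (1.0 / v_bd**2 - h1 * h1)


def rate_for_time_bound(h1: float, c_bd: float, e_rest: float = 0.05,
                        delta: float = 1.0) -> float:
    """Smallest rate whose convergence time is at most ``c_bd`` seconds.

    With ``rho = E_rest^(delta/C_bd)`` the closed form is
    ``s = (1 - rho)^2 / (h1 rho)``, algebraically identical to
    ``s = (C_time / (4 h1^2)) (1/C_time - 4 h1)^2`` with
    ``C_time = rho / (4 h1)``.
    """
    if not (h1 > 0 and c_bd > 0 and 0 < e_rest < 1):
        raise ValueError("need h1 > 0, c_bd > 0 and e_rest in (0, 1)")
    rho = e_rest ** (delta / c_bd)
    s_closed = (1.0 - rho) ** 2 / (h1 * rho)
    c_time = rho / (4.0 * h1)
    s_printed = (c_time / (4.0 * h1 * h1)) * (1.0 / c_time - 4.0 * h1) ** 2
    if not np.isclose(s_closed, s_printed, rtol=1e-10, atol=0.0):
        raise AssertionError("the two algebraic forms of the time-bound rate disagree")
    return float(s_closed)


def conservative_rate(range_lo: float, range_hi: float, objective: str,
                      bound_value: float, context: dict) -> float:
    """Rate selection over a nuisance range (noise variance or rate scale).

    The information eigenvalue ``h1`` is monotone in the nuisance, and each
    inverse map is monotone in ``h1``; computing the rate at both range
    extremes and taking the conservative one (min for the error bound, max for
    the time bound) therefore covers the whole range.

    ``context`` supplies ``h1_of`` — a callable mapping a nuisance value to the
    smallest information eigenvalue — plus ``e_rest``/``delta`` for the time
    objective.
    """
    if not (0 < range_lo <= range_hi):
        raise ValueError("need 0 < range_lo <= range_hi")
    h1_of = context["h1_of"]
    candidates = []
    for z in (range_lo, range_hi):
        h1 = h1_of(z)
        if objective == "error_bound":
            candidates.append(rate_for_error_bound(h1, bound_value))
        elif objective == "time_bound":
            candidates.append(
                rate_for_time_bound(h1, bound_value,
                                    context.get("e_rest", 0.05),
                                    context.get("delta", 1.0))
            )
        else:
            raise ValueError(f"unknown objective {objective!r}")
    return min(candidates) if objective == "error_bound" else max(candidates)


def admissible_interval(info: AverageInformation, v_bd: float, c_bd: float,
                        e_rest: float = 0.05, delta: float = 1.0):
    """Interval of rates meeting both bounds, or ``None`` if incompatible."""
    s_hi = rate_for_error_bound(info.h1, v_bd)
    s_lo = rate_for_time_bound(info.h1, c_bd, e_rest, delta)
    if s_lo > s_hi:
        return None
    return (float(s_lo), float(s_hi))


class LearningRateCalibrator:
    """Sklearn-style front end: fit the average information, pick the rate.

    Parameters
    ----------
    kind : {'gaussian', 'point_process'}
        Observation family of the channel being calibrated.
    Z : float or (lo, hi) tuple, optional
        Noise variance (Gaussian kind).  A tuple triggers conservative
        selection over the range.
    phi_star : array or None
        True parameters (point-process kind); if None, ``rate_range`` gives the
        (min, max) firing-rate extremes used conservatively.
    rate_range : (lo, hi) tuple of Hz, optional
        Firing-rate extremes for conservative point-process calibration.
    delta : float
        Bin width in seconds.
    v_bd, c_bd, e_rest : floats
        Exactly one of ``v_bd`` (covariance-norm bound) / ``c_bd``
        (convergence-time bound, seconds) should be set.
    """

    def __init__(self, kind="gaussian", Z=None, phi_star=None, rate_range=None,
                 delta=1.0, v_bd=None, c_bd=None, e_rest=0.05):
        self.kind = kind
        self.Z = Z
        self.phi_star = phi_star
        self.rate_range = rate_range
        self.delta = delta
        self.v_bd = v_bd
        self.c_bd = c_bd
        self.e_rest = e_rest

    def get_params(self, deep=True):
        return dict(kind=self.kind, Z=self.Z, phi_star=self.phi_star,
                    rate_range=self.rate_range, delta=self.delta,
                    v_bd=self.v_bd, c_bd=self.c_bd, e_rest=self.e_rest)

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _info_from(self, V, scale):
        if self.kind == "gaussian":
            return average_information_gaussian(V, scale)
        # point process with a flat nuisance rate: lambda*delta plays 1/Z
        return average_information_gaussian(V, 1.0 / (scale * self.delta))

    def fit(self, V, y=None):
        """Compute the average information from regressors ``V`` (T x (1+d)).

        Rows may be raw velocities (a leading 1 is prepended) or ready
        regressors whose first column is exactly 1.
        """
        V = np.asarray(V, dtype=float)
        if V.ndim != 2:
            raise ValueError("V must be 2-D (time x features)")
        if not np.allclose(V[:, 0], 1.0):
            V = np.column_stack([np.ones(len(V)), V])

        if self.kind == "gaussian":
            if self.Z is None:
                raise ValueError("gaussian calibration requires Z")
            z = np.atleast_1d(np.asarray(self.Z, dtype=float))
            self.info_ = average_information_gaussian(V, float(np.mean(z)))
            nuisance = (float(z.min()), float(z.max()))
            h1_of = lambda Z: average_information_gaussian(V, Z).h1  # noqa: E731
        elif self.kind == "point_process":
            if self.phi_star is not None:
                self.info_ = average_information_point_process(V, self.phi_star, self.delta)
                lam_mid = float(np.exp(np.asarray(self.phi_star).ravel()[0]))
                nuisance = (lam_mid, lam_mid)
            elif self.rate_range is not None:
                lo, hi = self.rate_range
                mid = np.sqrt(lo * hi)
                self.info_ = self._info_from(V, mid)
                nuisance = (float(lo), float(hi))
            else:
                raise ValueError("point-process calibration needs phi_star or rate_range")
            h1_of = lambda lam: self._info_from(V, lam).h1  # noqa: E731
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

        if (self.v_bd is None) == (self.c_bd is None):
            raise ValueError("set exactly one of v_bd or c_bd")
        ctx = {"h1_of": h1_of, "e_rest": self.e_rest, "delta": self.delta}
        if self.v_bd is not None:
            s = conservative_rate(nuisance[0], nuisance[1], "error_bound", self.v_bd, ctx)
        else:
            s = conservative_rate(nuisance[0], nuisance[1], "time_bound", self.c_bd, ctx)

        self.learning_rate_ = float(s)
        self.result_ = CalibrationResult(
            learning_rate=self.learning_rate_,
            predicted_cov=steady_state_covariance(self.info_, s),
            predicted_factor=convergence_factor(self.info_, s),
            predicted_convergence_time=predict_convergence_time(
                self.info_, s, self.e_rest, self.delta),
        )
        return self
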