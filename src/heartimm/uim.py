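"""Autoregressive uncertainty model for irregular heart rhythm.

Arrhythmic motion is modelled as an AR(p) process

    y_k = A_1 y_{k-1} + ... + A_p y_{k-p} + v_k,

realized in companion (canonical) state-space form and tracked by a
Kalman filter whose process noise is deliberately inflated: the point of
this model is not to explain the irregular dynamics but to follow them
with a wide bandwidth.  Coefficients are re-estimated every sample by
exponentially weighted recursive least squares (RLS) so the predictor
adapts when the rhythm changes abruptly.  Orders 8 and 12 are the two
stock variants (UIM8 / UIM12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filtering import (
    GaussianBelief,
    LinearModelSpec,
    kf_predict,
    kf_update,
    multi_step_predict,
)
from .trace import SignalTrace

__all__ = [
    "ArCoefficients",
    "ArStateSpace",
    "companion_from_coeffs",
    "companion_matrix",
    "estimate_ar_rls",
    "RlsEstimator",
    "build_uim",
    "UimPredictor",
    "default_forgetting",
]

logger = logging.getLogger(__name__)

RLS_DELTA = 1e3  # initial inverse-correlation scale δ·I


@dataclass
class ArCoefficients:
    """AR(p) coefficients with the innovation (driving-noise) variance."""

    coeffs: np.ndarray
    innovation_variance: float = 0.0

    def __post_init__(self):
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.ndim != 1 or self.coeffs.size < 1:
            raise ValueError("need at least one AR coefficient")
        if self.innovation_variance < 0:
            raise ValueError("innovation variance must be >= 0")

    @property
    def order(self) -> int:
        return self.coeffs.size


@dataclass
class ArStateSpace:
    """Companion-form realization of an AR(p) model.

    First transition row carries A_1..A_p, the subdiagonal is identity;
    noise enters, and the observation reads, the first state component.
    """

    transition: np.ndarray
    noise_input: np.ndarray
    observation: np.ndarray
    process_noise_var: float
    measurement_noise_var: float

    @property
    def order(self) -> int:
        return self.transition.shape[0]

    def as_linear_spec(self) -> LinearModelSpec:
        return LinearModelSpec(
            transition=self.transition,
            observation=self.observation,
            process_noise_cov=np.array([[self.process_noise_var]]),
            measurement_noise_cov=np.array([[self.measurement_noise_var]]),
            noise_input=self.noise_input,
        )


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    p = coeffs.size
    F = np.zeros((p, p))
    F[0, :] = coeffs
    if p > 1:
        F[1:, :-1] = np.eye(p - 1)
    return F


def companion_from_coeffs(
    coeffs: ArCoefficients,
    measurement_noise_var: float = 0.0,
    q_scale: float = 1.0,
) -> ArStateSpace:
    """Build the companion state space from AR coefficients.

    The process noise variance is the (possibly inflated) innovation
    variance; ``q_scale`` applies the inflation.
    """
    p = coeffs.order
    if p < 1:
        raise ValueError("AR order must be >= 1")
    F = companion_matrix(coeffs.coeffs)
    B = np.zeros((p, 1))
    B[0, 0] = 1.0
    C = np.zeros((1, p))
    C[0, 0] = 1.0
    return ArStateSpace(
        transition=F,
        noise_input=B,
        observation=C,
        process_noise_var=q_scale * coeffs.innovation_variance,
        measurement_noise_var=measurement_noise_var,
    )


def default_forgetting(dt: float, resp_period_s: float = 4.0) -> float:
    """λ with memory horizon 1/(1−λ) covering one respiratory period."""
    lam = 1.0 - dt / resp_period_s
    return float(min(max(lam, 0.5), 1.0))


class RlsEstimator:
    """Exponentially weighted RLS for AR coefficients.

    State: coefficient vector θ (p,), inverse-correlation matrix P
    initialized to δ·I, and an exponentially weighted estimate of the
    innovation variance from the prediction residuals.
    """

    def __init__(self, order: int, forgetting: float, delta: float = RLS_DELTA):
        if order < 1:
            raise ValueError("AR order must be >= 1")
        if not (0.0 < forgetting <= 1.0):
            raise ValueError("forgetting factor must lie in (0, 1]")
        self.order = order
        self.lam = float(forgetting)
        self.theta = np.zeros(order)
        self.P = delta * np.eye(order)
        self.var = 0.0
        self._var_weight = 0.0

    def step(self, phi: np.ndarray, y: float) -> float:
        """One RLS update from regressor φ (past samples) and target y.

        Returns the a-priori residual.
        """
        Pphi = self.P @ phi
        denom = self.lam + float(phi @ Pphi)
        gain = Pphi / denom
        err = float(y - self.theta @ phi)
        self.theta = self.theta + gain * err
        self.P = (self.P - np.outer(gain, Pphi)) / self.lam
        # EW average of squared residuals (normalized so it is unbiased
        # during the start-up transient)
        self._var_weight = self.lam * self._var_weight + 1.0
        self.var += (err * err - self.var) / self._var_weight
        return err

    def coefficients(self) -> ArCoefficients:
        return ArCoefficients(self.theta.copy(), self.var)


def estimate_ar_rls(
    signal: SignalTrace | np.ndarray,
    order: int,
    forgetting: float = 1.0,
    delta: float = RLS_DELTA,
) -> tuple[np.ndarray, np.ndarray]:
    """Run RLS over a whole series; per-step coefficient estimates.

    Returns ``(coeff_path, var_path)`` where ``coeff_path[k]`` holds the
    estimate after processing sample ``k`` (first ``order`` rows are the
    zero initialization — no full regressor exists yet).  No mean removal
    is applied here; the model is zero-mean by construction.
    """
    y = signal.channel(0) if isinstance(signal, SignalTrace) else np.asarray(
        signal, dtype=float
    )
    n = y.shape[0]
    if n <= order:
        raise ValueError("signal must be longer than the AR order")
    est = RlsEstimator(order, forgetting, delta)
    coeff_path = np.zeros((n, order))
    var_path = np.zeros(n)
    for k in range(order, n):
        phi = y[k - order : k][::-1]  # most recent sample first
        est.step(phi, y[k])
        coeff_path[k] = est.theta
        var_path[k] = est.var
    return coeff_path, var_path


def build_uim(
    coeffs: ArCoefficients,
    q_scale: float = 10.0,
    measurement_noise_var: float = 1e-6,
) -> ArStateSpace:
    """Companion model with loosely chosen (inflated) process noise.

    ``q_scale`` multiplies the estimated innovation variance; values below
    1 defeat the purpose of the wide-bandwidth model and are accepted with
    a warning.
    """
    if q_scale < 1.0:
        logger.warning(
            "q_scale=%g < 1 narrows the uncertainty model's bandwidth", q_scale
        )
    return companion_from_coeffs(
        coeffs, measurement_noise_var=measurement_noise_var, q_scale=q_scale
    )


class UimPredictor:
    """Adaptive AR(p) Kalman predictor (UIM8 / UIM12).

    Each sample: subtract an exponentially weighted running mean, update
    the RLS coefficient estimate, rebuild the companion model, and run one
    KF predict/update on the demeaned signal.  Predictions add the mean
    back.  Estimated coefficients are *not* stability-projected; transient
    explosive estimates are tolerated and the KF remains well defined.
    """

    family = "uim"

    def __init__(
        self,
        order: int = 8,
        forgetting: float | None = None,
        q_scale: float = 10.0,
        measurement_noise_var: float = 1e-6,
        dt: float = 0.01,
    ):
        self.order = order
        self.lam = default_forgetting(dt) if forgetting is None else float(forgetting)
        self.q_scale = q_scale
        self.r_meas = measurement_noise_var
        self.dt = dt
        self.name = f"UIM{order}"
        self.rls = RlsEstimator(order, self.lam)
        self.mean_est = 0.0
        self._mean_weight = 0.0
        self.history = np.zeros(order)  # most recent demeaned samples, newest first
        self._n_seen = 0
        self.belief = GaussianBelief(
            np.zeros(order), 1e-2 * np.eye(order)
        )

    # -- warm start -----------------------------------------------------
    def warm_up(self, values: np.ndarray) -> None:
        """Feed an initial stretch of samples (e.g. the tuning window)."""
        for z in np.asarray(values, dtype=float):
            self.update(z)

    def _update_mean(self, z: float) -> None:
        self._mean_weight = self.lam * self._mean_weight + 1.0
        self.mean_est += (z - self.mean_est) / self._mean_weight

    def _spec(self) -> LinearModelSpec:
        coeffs = self.rls.coefficients()
        # floor keeps the KF well defined before the variance estimate warms up
        coeffs.innovation_variance = max(coeffs.innovation_variance, 1e-10)
        return build_uim(
            coeffs, q_scale=self.q_scale, measurement_noise_var=self.r_meas
        ).as_linear_spec()

    # -- protocol -------------------------------------------------------
    def predicted_measurement(self) -> tuple[float, float]:
        spec = self._spec()
        zhat = float((spec.observation @ self.belief.mean)[0]) + self.mean_est
        var = float(
            (spec.observation @ self.belief.covariance @ spec.observation.T)[0, 0]
        )
        return zhat, var

    def forecast(self, horizon: int) -> list[tuple[float, float]]:
        spec = self._spec()
        steps = multi_step_predict(self.belief, spec, horizon)
        return [(z + self.mean_est, var) for z, var in steps]

    def update(self, z: float):
        """Advance one sample; returns (prior prediction, prior variance,
        innovation)."""
        z = float(z)
        self._update_mean(z)
        zc = z - self.mean_est
        if self._n_seen >= self.order:
            self.rls.step(self.history.copy(), zc)
        spec = self._spec()
        prior = kf_predict(self.belief, spec)
        zpred = float((spec.observation @ prior.mean)[0]) + self.mean_est
        post, innov = kf_update(prior, zc, spec, mode_name=self.name)
        var = float(innov.covariance[0, 0])
        self.belief = post
        self.history = np.roll(self.history, 1)
        self.history[0] = zc
        self._n_seen += 1
        return zpred, var, innov

    # -- fusion hooks ---------------------------------------------------
    def apply_anchor(self, delta: float, extra_var: float) -> None:
        """Re-anchor the most-recent-sample state component."""
        self.belief.mean[0] += delta
        self.belief.covariance[0, 0] += extra_var

    def clone(self) -> "UimPredictor":
        other = UimPredictor.__new__(UimPredictor)
        other.__dict__.update(self.__dict__)
        other.rls = RlsEstimator(self.order, self.lam)
        other.rls.theta = self.rls.theta.copy()
        other.rls.P = self.rls.P.copy()
        other.rls.var = self.rls.var
        other.rls._var_weight = self.rls._var_weight
        other.history = self.history.copy()
        other.belief = self.belief.copy()
        return other
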