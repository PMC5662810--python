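"""Linear-Gaussian filtering primitives shared by every model in the bank.

The harmonic tracker, the autoregressive filters and the fusion cycle all
reduce each step to the same small set of operations on a Gaussian belief:
time propagation, measurement update, and the Gaussian innovation
likelihood that re-weights the model bank.  Numerical hygiene lives here:
Joseph-form updates, Cholesky solves (never explicit inverses), and
re-symmetrization of every covariance that leaves this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "GaussianBelief",
    "LinearModelSpec",
    "Innovation",
    "NumericalDegeneracyError",
    "kf_predict",
    "kf_update",
    "update_with_residual",
    "gaussian_log_likelihood",
    "gaussian_likelihood",
    "multi_step_predict",
    "symmetrize",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class NumericalDegeneracyError(RuntimeError):
    """Raised when an innovation covariance loses positive definiteness."""


def symmetrize(P: np.ndarray) -> np.ndarray:
    """Return ``(P + P.T) / 2`` — drift accumulates over thousands of steps."""
    return 0.5 * (P + P.T)


@dataclass
class GaussianBelief:
    """Filter state for one mode: mean vector and covariance matrix."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        n = self.mean.shape[0]
        if self.covariance.shape != (n, n):
            raise ValueError(
                f"covariance shape {self.covariance.shape} does not match "
                f"mean length {n}"
            )

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def copy(self) -> "GaussianBelief":
        return GaussianBelief(self.mean.copy(), self.covariance.copy())


@dataclass
class LinearModelSpec:
    """Linear state-space model x' = F x + B w,  z = H x + v.

    ``process_noise_cov`` is the covariance of w, ``measurement_noise_cov``
    the covariance of v.  H is stored as a (d, n) matrix with d the
    measurement dimension (d = 1 throughout this package).
    """

    transition: np.ndarray
    observation: np.ndarray
    process_noise_cov: np.ndarray
    measurement_noise_cov: np.ndarray
    noise_input: np.ndarray | None = None

    def __post_init__(self):
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.observation = np.atleast_2d(np.asarray(self.observation, dtype=float))
        self.process_noise_cov = np.atleast_2d(
            np.asarray(self.process_noise_cov, dtype=float)
        )
        self.measurement_noise_cov = np.atleast_2d(
            np.asarray(self.measurement_noise_cov, dtype=float)
        )
        n = self.transition.shape[0]
        if self.transition.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if self.observation.shape[1] != n:
            raise ValueError("observation column count must match state dim")
        if self.noise_input is None:
            self.noise_input = np.eye(n)
        else:
            self.noise_input = np.atleast_2d(
                np.asarray(self.noise_input, dtype=float)
            )
            if self.noise_input.ndim == 2 and self.noise_input.shape[0] != n:
                # allow a column vector passed as 1-d
                if self.noise_input.shape == (1, n):
                    self.noise_input = self.noise_input.T
                else:
                    raise ValueError("noise_input row count must match state dim")
        q = self.process_noise_cov.shape[0]
        if self.noise_input.shape[1] != q:
            raise ValueError("noise_input columns must match process noise dim")

    @property
    def dim(self) -> int:
        return self.transition.shape[0]

    @property
    def effective_process_cov(self) -> np.ndarray:
        """B Q Bᵀ in state coordinates."""
        B = self.noise_input
        return B @ self.process_noise_cov @ B.T


@dataclass
class Innovation:
    """Measurement residual v, its covariance S, and log N(v; 0, S)."""

    residual: np.ndarray
    covariance: np.ndarray
    log_likelihood: float

    def __post_init__(self):
        self.residual = np.atleast_1d(np.asarray(self.residual, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))


def kf_predict(belief: GaussianBelief, model: LinearModelSpec) -> GaussianBelief:
    """Time update: mean ← F·mean, P ← F P Fᵀ + B Q Bᵀ."""
    F = model.transition
    if F.shape[0] != belief.dim:
        raise ValueError(
            f"model dimension {F.shape[0]} does not match belief dimension "
            f"{belief.dim}"
        )
    mean = F @ belief.mean
    P = symmetrize(F @ belief.covariance @ F.T + model.effective_process_cov)
    return GaussianBelief(mean, P)


def _log_density(v: np.ndarray, chol: np.ndarray) -> float:
    """log N(v; 0, S) from the Cholesky factor of S."""
    alpha = linalg.solve_triangular(chol, v, lower=True)
    log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
    d = v.shape[0]
    return -0.5 * (d * LOG_2PI + log_det + float(alpha @ alpha))


def update_with_residual(
    belief: GaussianBelief,
    residual: np.ndarray,
    H: np.ndarray,
    R: np.ndarray,
    mode_name: str = "",
) -> tuple[GaussianBelief, Innovation]:
    """Joseph-form measurement update from a precomputed residual.

    The residual is supplied by the caller so that nonlinear measurement
    functions (EKF) can use ``z - h(mean)`` while sharing the same gain,
    covariance and likelihood arithmetic as the linear update.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    v = np.atleast_1d(np.asarray(residual, dtype=float))
    S = symmetrize(H @ belief.covariance @ H.T + R)
    try:
        chol = linalg.cholesky(S, lower=True)
    except linalg.LinAlgError as exc:
        label = f" in mode {mode_name!r}" if mode_name else ""
        raise NumericalDegeneracyError(
            f"innovation covariance not positive definite{label}: {exc}"
        ) from exc
    PHt = belief.covariance @ H.T
    K = linalg.cho_solve((chol, True), PHt.T).T
    mean = belief.mean + K @ v
    n = belief.dim
    IKH = np.eye(n) - K @ H
    P = IKH @ belief.covariance @ IKH.T + K @ R @ K.T
    post = GaussianBelief(mean, symmetrize(P))
    innov = Innovation(v, S, _log_density(v, chol))
    return post, innov


def kf_update(
    belief: GaussianBelief,
    z,
    model: LinearModelSpec,
    mode_name: str = "",
) -> tuple[GaussianBelief, Innovation]:
    """Measurement update of a *predicted* belief, Joseph form.

    Returns the posterior belief and the innovation (residual,
    covariance, log-likelihood).
    """
    H = model.observation
    z = np.atleast_1d(np.asarray(z, dtype=float))
    v = z - H @ belief.mean
    return update_with_residual(
        belief, v, H, model.measurement_noise_cov, mode_name
    )


def gaussian_log_likelihood(innovation: Innovation) -> float:
    """Log of the Gaussian innovation density (the bank's mode likelihood)."""
    return float(innovation.log_likelihood)


def gaussian_likelihood(innovation: Innovation) -> float:
    """Λ = N(v; 0, S), exponentiated from the log domain.

    Exponentiation happens only here; the fusion cycle normalizes in the
    log domain first so large arrhythmia residuals cannot underflow the
    whole bank at once.
    """
    return float(np.exp(innovation.log_likelihood))


def multi_step_predict(
    belief: GaussianBelief, model: LinearModelSpec, horizon: int
) -> list[tuple[float, float]]:
    """Iterate the time update ``horizon`` times without measurements.

    Element ``h`` (0-based) is the measurement-space prediction
    ``H·F^(h+1)·mean`` with variance ``H·P_(h+1)·Hᵀ + R``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    H = model.observation
    R = model.measurement_noise_cov
    out = []
    current = belief
    for _ in range(horizon):
        current = kf_predict(current, model)
        zhat = H @ current.mean
        var = H @ current.covariance @ H.T + R
        out.append((float(zhat[0]), float(var[0, 0])))
    return out
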