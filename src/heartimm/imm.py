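"""Interacting-multiple-model fusion cycle over a heterogeneous filter bank.

Each cycle runs the classic four IMM stages over a bank of r modes
governed by a Markov switching chain with transition matrix p_ij:

1. *Interaction / mixing* — mixing probabilities
   μ_{i|j} = p_ij μ_i / Σ_i p_ij μ_i feed a probability-weighted blend of
   the per-mode estimates into each filter.
2. *Per-mode filtering* — every mode runs its own predict/update (EKF for
   the harmonic model, KF for the AR models).
3. *Mode-probability update* — the Gaussian innovation likelihood Λ_j
   re-weights the predicted mode probabilities,
   μ_j ∝ μ_j(k+1|k) Λ_j, handled in the log domain with max-subtraction.
4. *Combination* — the bank output is the probability-weighted mixture of
   per-mode predictions with the mixture spread term added to the
   variance.

The harmonic and AR modes live in state spaces of different dimension and
meaning, so full-state mixing between them is undefined.  The default
cross-family converter is *output-level re-anchoring*: foreign modes
contribute their predicted measurement, which shifts the receiving mode's
offset / most-recent-sample component, and the mixture spread inflates
that component's variance.  Same-family, same-dimension banks use the
full state-space mixing; a probabilities-only mode (no state exchange,
i.e. an autonomous multiple-model bank) is available for ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .filtering import GaussianBelief, symmetrize

__all__ = [
    "ModeSet",
    "ImmStepResult",
    "mixing_probabilities",
    "mix_states",
    "combine_output",
    "imm_step",
    "sojourn_transition_matrix",
    "ImmPredictor",
]

logger = logging.getLogger(__name__)

MIXING_SCHEMES = ("full", "output_anchor", "probabilities_only")


def sojourn_transition_matrix(expected_sojourn_steps, r: int | None = None) -> np.ndarray:
    """Row-stochastic switching matrix from expected regime dwell times.

    ``p_ii = 1 - 1/τ_i`` with the leave probability spread uniformly over
    the other modes.  Sojourn times are in *steps* and must exceed 1.
    """
    tau = np.atleast_1d(np.asarray(expected_sojourn_steps, dtype=float))
    if r is None:
        r = tau.size
    if tau.size != r:
        raise ValueError("one sojourn time per mode required")
    if np.any(tau <= 1.0):
        raise ValueError("expected sojourn times must exceed 1 step")
    P = np.zeros((r, r))
    for i in range(r):
        stay = 1.0 - 1.0 / tau[i]
        P[i, :] = (1.0 - stay) / (r - 1) if r > 1 else 0.0
        P[i, i] = stay if r > 1 else 1.0
    return P


@dataclass
class ModeSet:
    """The filter bank: mode handles, switching matrix and mode probabilities."""

    modes: list
    transition_matrix: np.ndarray
    mode_probs: np.ndarray
    mixing: str = "output_anchor"

    def __post_init__(self):
        self.transition_matrix = np.atleast_2d(
            np.asarray(self.transition_matrix, dtype=float)
        )
        self.mode_probs = np.atleast_1d(np.asarray(self.mode_probs, dtype=float))
        r = len(self.modes)
        if self.transition_matrix.shape != (r, r):
            raise ValueError("transition matrix must be r x r")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transition_matrix < 0) or np.any(self.transition_matrix > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if abs(self.mode_probs.sum() - 1.0) > 1e-12 or np.any(self.mode_probs < 0):
            raise ValueError("mode probabilities must form a probability vector")
        if self.mixing not in MIXING_SCHEMES:
            raise ValueError(f"mixing must be one of {MIXING_SCHEMES}")
        if self.mixing == "full":
            dims = {m.belief.dim for m in self.modes}
            fams = {m.family for m in self.modes}
            if len(dims) > 1 or len(fams) > 1:
                raise ValueError(
                    "full state mixing requires a same-family, same-dimension "
                    "bank; no converter exists between "
                    f"families {sorted(fams)} with dimensions {sorted(dims)} — "
                    "use mixing='output_anchor'"
                )

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def mode_names(self) -> list:
        return [m.name for m in self.modes]


@dataclass
class ImmStepResult:
    """Everything one fusion cycle produces."""

    combined_prediction: float
    combined_prediction_var: float
    combined_filtered: float
    combined_filtered_var: float
    mode_probs: np.ndarray
    predicted_mode_probs: np.ndarray
    per_mode_predictions: np.ndarray
    per_mode_variances: np.ndarray
    log_likelihoods: np.ndarray
    innovations: list = field(default_factory=list)


def mixing_probabilities(mode_set: ModeSet) -> tuple[np.ndarray, np.ndarray]:
    """Mixing matrix μ_{i|j} (column j mixes into mode j) and the predicted
    mode probabilities μ_j(k+1|k) = Σ_i p_ij μ_i.

    A predicted probability below 1e-30 would make its column 0/0; that
    column is set uniform with a logged warning.
    """
    P = mode_set.transition_matrix
    mu = mode_set.mode_probs
    r = mode_set.n_modes
    mu_pred = P.T @ mu
    mix = np.empty((r, r))
    for j in range(r):
        if mu_pred[j] < 1e-30:
            logger.warning(
                "predicted probability of mode %s underflowed; "
                "mixing column set uniform", mode_set.mode_names[j],
            )
            mix[:, j] = 1.0 / r
        else:
            mix[:, j] = P[:, j] * mu / mu_pred[j]
    return mix, mu_pred


def mix_gaussians(beliefs: list[GaussianBelief], weights: np.ndarray) -> GaussianBelief:
    """Probability-weighted Gaussian moment match: mixture mean and the
    mixture covariance including the spread (disagreement) term."""
    means = np.stack([b.mean for b in beliefs])
    mixed_mean = weights @ means
    P = np.zeros_like(beliefs[0].covariance)
    for w, b in zip(weights, beliefs):
        d = b.mean - mixed_mean
        P += w * (b.covariance + np.outer(d, d))
    return GaussianBelief(mixed_mean, symmetrize(P))


def mix_states(mode_set: ModeSet, mixing_matrix: np.ndarray) -> None:
    """Apply the interaction stage in place, per the configured scheme."""
    if mode_set.mixing == "probabilities_only":
        return
    modes = mode_set.modes
    r = len(modes)
    if mode_set.mixing == "full":
        pre = [m.belief.copy() for m in modes]
        for j in range(r):
            modes[j].belief = mix_gaussians(pre, mixing_matrix[:, j])
        return
    # output-level re-anchoring for heterogeneous banks
    zhat = np.empty(r)
    svar = np.empty(r)
    for i, m in enumerate(modes):
        zhat[i], svar[i] = m.predicted_measurement()
    for j in range(r):
        w = mixing_matrix[:, j]
        z_mix = float(w @ zhat)
        spread = float(w @ (zhat - z_mix) ** 2)
        modes[j].apply_anchor(z_mix - zhat[j], spread)


def combine_output(predictions, variances, mode_probs) -> tuple[float, float]:
    """Mixture mean and variance of the per-mode measurement predictions:
    variance carries each mode's own variance plus the spread term."""
    z = np.atleast_1d(np.asarray(predictions, dtype=float))
    s = np.atleast_1d(np.asarray(variances, dtype=float))
    mu = np.atleast_1d(np.asarray(mode_probs, dtype=float))
    mean = float(mu @ z)
    var = float(mu @ (s + (z - mean) ** 2))
    return mean, var


def imm_step(mode_set: ModeSet, z: float) -> ImmStepResult:
    """One full fusion cycle on measurement z (in place on the bank)."""
    mix, mu_pred = mixing_probabilities(mode_set)
    mix_states(mode_set, mix)

    r = mode_set.n_modes
    zpred = np.empty(r)
    pvar = np.empty(r)
    loglik = np.empty(r)
    innovations = []
    for i, mode in enumerate(mode_set.modes):
        zpred[i], pvar[i], innov = mode.update(z)
        loglik[i] = innov.log_likelihood
        innovations.append(innov)

    # mode-probability update in the log domain
    finite = np.isfinite(loglik)
    if not np.any(finite):
        logger.warning("all mode likelihoods underflowed; keeping predicted μ")
        mu_new = mu_pred.copy()
    else:
        shifted = loglik - np.max(loglik[finite])
        weights = np.where(finite, np.exp(np.clip(shifted, -745.0, 0.0)), 0.0)
        unnorm = mu_pred * weights
        total = unnorm.sum()
        if total <= 0.0:
            logger.warning("mode posterior underflowed; keeping predicted μ")
            mu_new = mu_pred.copy()
        else:
            mu_new = unnorm / total
    mode_set.mode_probs = mu_new

    comb_pred, comb_pred_var = combine_output(zpred, pvar, mu_pred)
    zf = np.empty(r)
    vf = np.empty(r)
    for i, mode in enumerate(mode_set.modes):
        zf[i], vf[i] = mode.predicted_measurement()
    comb_filt, comb_filt_var = combine_output(zf, vf, mu_new)

    return ImmStepResult(
        combined_prediction=comb_pred,
        combined_prediction_var=comb_pred_var,
        combined_filtered=comb_filt,
        combined_filtered_var=comb_filt_var,
        mode_probs=mu_new.copy(),
        predicted_mode_probs=mu_pred,
        per_mode_predictions=zpred,
        per_mode_variances=pvar,
        log_likelihoods=loglik,
        innovations=innovations,
    )


class ImmPredictor:
    """Online predictor running the fusion cycle over a mode bank.

    Exposes the same protocol as the individual predictors so the
    evaluation harness treats single models and banks uniformly.
    """

    family = "imm"

    def __init__(
        self,
        modes: list,
        transition_matrix,
        mode_probs,
        mixing: str = "output_anchor",
        name: str = "IMM",
        sqi_hook=None,
        sqi_window: int = 100,
    ):
        self.mode_set = ModeSet(
            modes=modes,
            transition_matrix=transition_matrix,
            mode_probs=mode_probs,
            mixing=mixing,
        )
        self.name = name
        self.last_result: ImmStepResult | None = None
        self._low_mu_steps = np.zeros(len(modes), dtype=int)
        #: optional signal-quality adaptation of the switching rates: a
        #: callable mapping the recent sample window to a score in [0, 1];
        #: the off-diagonal transition rates are scaled by that score
        #: (rows renormalized).  Disabled (None) by default.
        self.sqi_hook = sqi_hook
        self._sqi_window = int(sqi_window)
        self._sqi_buffer: list[float] = []
        self._base_transition = self.mode_set.transition_matrix.copy()

    def _apply_sqi(self, z: float) -> None:
        self._sqi_buffer.append(float(z))
        if len(self._sqi_buffer) > self._sqi_window:
            del self._sqi_buffer[: len(self._sqi_buffer) - self._sqi_window]
        score = float(self.sqi_hook(np.asarray(self._sqi_buffer)))
        score = float(np.clip(score, 0.0, 1.0))
        P = self._base_transition.copy()
        r = P.shape[0]
        off = ~np.eye(r, dtype=bool)
        P[off] *= score
        P[np.eye(r, dtype=bool)] = 1.0 - P.sum(axis=1) + np.diag(P)
        self.mode_set.transition_matrix = P

    @property
    def mode_probs(self) -> np.ndarray:
        return self.mode_set.mode_probs

    # -- protocol -------------------------------------------------------
    def predicted_measurement(self) -> tuple[float, float]:
        r = self.mode_set.n_modes
        z = np.empty(r)
        v = np.empty(r)
        for i, m in enumerate(self.mode_set.modes):
            z[i], v[i] = m.predicted_measurement()
        return combine_output(z, v, self.mode_set.mode_probs)

    def forecast(self, horizon: int) -> list[tuple[float, float]]:
        """Multi-step extrapolation: per-mode forecasts combined under the
        Markov-propagated mode probabilities, no mutation."""
        per_mode = [m.forecast(horizon) for m in self.mode_set.modes]
        P = self.mode_set.transition_matrix
        mu = self.mode_set.mode_probs.copy()
        out = []
        for h in range(horizon):
            mu = P.T @ mu
            z = [per_mode[i][h][0] for i in range(len(per_mode))]
            v = [per_mode[i][h][1] for i in range(len(per_mode))]
            out.append(combine_output(z, v, mu))
        return out

    #: a mode whose probability stays below this level for LOW_MU_S seconds
    #: is considered written off and is hinted to re-acquire its state
    LOW_MU = 0.2
    LOW_MU_S = 2.0

    def update(self, z: float):
        if self.sqi_hook is not None:
            self._apply_sqi(z)
        result = imm_step(self.mode_set, z)
        self.last_result = result
        for i, mode in enumerate(self.mode_set.modes):
            hint = getattr(mode, "reacquire_hint", None)
            dt = getattr(mode, "dt", None)
            if hint is None or not dt:
                continue
            if result.mode_probs[i] < self.LOW_MU:
                self._low_mu_steps[i] += 1
                if self._low_mu_steps[i] * dt > self.LOW_MU_S:
                    hint()
                    self._low_mu_steps[i] = 0
            else:
                self._low_mu_steps[i] = 0
        return result.combined_prediction, result.combined_prediction_var, result

    def apply_anchor(self, delta: float, extra_var: float) -> None:
        for m in self.mode_set.modes:
            m.apply_anchor(delta, extra_var)
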