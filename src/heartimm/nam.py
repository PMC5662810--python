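"""Harmonic cardiorespiratory model tracked by an extended Kalman filter.

The regular-rhythm signal is modelled as a superposition of cardiac
harmonics, respiratory harmonics and quadratic cardiorespiratory
modulation terms,

    x(t) = c + Σ_k a_k^c cos θ_k^c + Σ_l a_l^r cos θ_l^r
             + Σ_{kl} a_kl^m cos θ_kl^m,

where the offset c, every amplitude a and the two base frequencies
f^c, f^r evolve as random walks while the phases integrate the base
frequencies with their harmonic multipliers:

    θ_k^c  += 2π k f^c Δt,
    θ_l^r  += 2π l f^r Δt,
    θ_kl^m += 2π (k f^c ± l f^r) Δt.

The modulation term is the product of the cardiac and respiratory
oscillations; a product of cosines expands into sum- and
difference-frequency sidebands, so the modulation frequencies are
*derived* as k·f^c ± l·f^r rather than carried as free states (a
``sum_only`` layout is available for a single sideband per pair).
The measurement is nonlinear in the state, hence the EKF with the
analytic Jacobians below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal as sp_signal

from .filtering import GaussianBelief, Innovation, symmetrize, update_with_residual
from .trace import SignalTrace

__all__ = [
    "HarmonicConfig",
    "NamNoise",
    "NamState",
    "InitializationError",
    "nam_transition",
    "nam_measure",
    "nam_measurement_jacobian",
    "nam_ekf_step",
    "nam_init_from_signal",
    "NamPredictor",
    "FREQ_FLOOR_HZ",
]

#: positivity floor applied to both base frequencies during filtering (Hz)
FREQ_FLOOR_HZ = 0.01

#: spectral search bands for initialization (Hz)
CARDIAC_BAND = (0.6, 3.5)
RESP_BAND = (0.05, 0.6)


class InitializationError(RuntimeError):
    """No usable spectral peak; supply frequencies explicitly."""


@dataclass(frozen=True)
class HarmonicConfig:
    """Harmonic counts and sampling interval of the modulated-sinusoid model.

    ``n_mod_cardiac``/``n_mod_resp`` bound how many low harmonics enter the
    quadratic modulation; with ``sum_and_difference`` each (k, l) pair
    contributes two sidebands at k·f^c ± l·f^r.
    """

    n_cardiac: int = 3
    n_resp: int = 2
    n_mod_cardiac: int = 1
    n_mod_resp: int = 1
    mod_sidebands: str = "sum_and_difference"
    dt: float = 0.01

    def __post_init__(self):
        if min(self.n_cardiac, self.n_resp, self.n_mod_cardiac, self.n_mod_resp) < 0:
            raise ValueError("harmonic counts must be >= 0")
        if self.n_mod_cardiac > self.n_cardiac or self.n_mod_resp > self.n_resp:
            raise ValueError("modulated harmonic counts cannot exceed totals")
        if self.mod_sidebands not in ("sum_only", "sum_and_difference"):
            raise ValueError("mod_sidebands must be sum_only or sum_and_difference")
        if self.dt < 0:
            raise ValueError("dt must be nonnegative")

    # -- modulation bookkeeping ----------------------------------------
    @property
    def mod_pairs(self) -> list[tuple[int, int, int]]:
        """Ordered (k, l, sign) triples, sign ∈ {+1, −1} per sideband."""
        signs = (1,) if self.mod_sidebands == "sum_only" else (1, -1)
        return [
            (k, l, s)
            for k in range(1, self.n_mod_cardiac + 1)
            for l in range(1, self.n_mod_resp + 1)
            for s in signs
        ]

    @property
    def n_mod(self) -> int:
        return len(self.mod_pairs)

    # -- flat state layout ---------------------------------------------
    # [c, a^c (Nc), a^r (Nr), a^m (M), f^c, f^r, θ^c (Nc), θ^r (Nr), θ^m (M)]
    @property
    def dim(self) -> int:
        return 3 + 2 * (self.n_cardiac + self.n_resp + self.n_mod)

    @property
    def idx_offset(self) -> int:
        return 0

    @property
    def sl_amp_c(self) -> slice:
        return slice(1, 1 + self.n_cardiac)

    @property
    def sl_amp_r(self) -> slice:
        a = 1 + self.n_cardiac
        return slice(a, a + self.n_resp)

    @property
    def sl_amp_m(self) -> slice:
        a = 1 + self.n_cardiac + self.n_resp
        return slice(a, a + self.n_mod)

    @property
    def idx_fc(self) -> int:
        return 1 + self.n_cardiac + self.n_resp + self.n_mod

    @property
    def idx_fr(self) -> int:
        return self.idx_fc + 1

    @property
    def sl_phase_c(self) -> slice:
        a = self.idx_fr + 1
        return slice(a, a + self.n_cardiac)

    @property
    def sl_phase_r(self) -> slice:
        a = self.idx_fr + 1 + self.n_cardiac
        return slice(a, a + self.n_resp)

    @property
    def sl_phase_m(self) -> slice:
        a = self.idx_fr + 1 + self.n_cardiac + self.n_resp
        return slice(a, a + self.n_mod)

    @property
    def sl_amplitudes(self) -> slice:
        return slice(1, 1 + self.n_cardiac + self.n_resp + self.n_mod)

    @property
    def sl_phases(self) -> slice:
        return slice(self.idx_fr + 1, self.dim)


@dataclass
class NamState:
    """Named view of the flat harmonic state vector (mainly for inspection)."""

    vector: np.ndarray
    config: HarmonicConfig

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (self.config.dim,):
            raise ValueError(
                f"state length {self.vector.shape} != layout dim {self.config.dim}"
            )

    @property
    def offset(self) -> float:
        return float(self.vector[self.config.idx_offset])

    @property
    def cardiac_amplitudes(self) -> np.ndarray:
        return self.vector[self.config.sl_amp_c]

    @property
    def resp_amplitudes(self) -> np.ndarray:
        return self.vector[self.config.sl_amp_r]

    @property
    def mod_amplitudes(self) -> np.ndarray:
        return self.vector[self.config.sl_amp_m]

    @property
    def f_cardiac(self) -> float:
        return float(self.vector[self.config.idx_fc])

    @property
    def f_resp(self) -> float:
        return float(self.vector[self.config.idx_fr])

    @property
    def cardiac_phases(self) -> np.ndarray:
        return self.vector[self.config.sl_phase_c]

    @property
    def resp_phases(self) -> np.ndarray:
        return self.vector[self.config.sl_phase_r]

    @property
    def mod_phases(self) -> np.ndarray:
        return self.vector[self.config.sl_phase_m]


@dataclass(frozen=True)
class NamNoise:
    """Diagonal process-noise scalars per block, and the measurement variance.

    q_amp covers the offset and every amplitude state, q_freq the two base
    frequencies, q_phase every phase state (all per-step variances).
    """

    q_amp: float = 1e-6
    q_freq: float = 1e-7
    q_phase: float = 1e-5
    r_meas: float = 1e-3
    #: amplitude magnitude bound (signal units): amplitude states are
    #: clamped into [-amp_limit, amp_limit] after each update.
    #: Arrhythmic misfit can otherwise run a slow component's amplitude
    #: away along the near-unidentifiable a·cos(θ)≈const direction.
    #: Set from the data scale at construction; inf disables.
    amp_limit: float = np.inf
    #: robust innovation gate (in innovation standard deviations): for a
    #: residual beyond the gate the measurement variance is inflated so the
    #: standardized residual sits exactly at the gate, bounding the
    #: influence any single foreign sample can exert on the harmonic state
    #: (Huber-style robust update).  The ungated innovation still feeds the
    #: mode likelihood.  Set to 0 to disable.
    gate_sigma: float = 5.0

    def diagonal(self, config: HarmonicConfig) -> np.ndarray:
        q = np.empty(config.dim)
        q[config.idx_offset] = self.q_amp
        q[config.sl_amplitudes] = self.q_amp
        q[config.idx_fc] = self.q_freq
        q[config.idx_fr] = self.q_freq
        q[config.sl_phases] = self.q_phase
        return q


def _phase_rates(x: np.ndarray, config: HarmonicConfig) -> np.ndarray:
    """dθ/dt for every phase state, in state order."""
    fc = x[config.idx_fc]
    fr = x[config.idx_fr]
    rates = np.empty(config.n_cardiac + config.n_resp + config.n_mod)
    rates[: config.n_cardiac] = [
        2.0 * np.pi * k * fc for k in range(1, config.n_cardiac + 1)
    ]
    rates[config.n_cardiac : config.n_cardiac + config.n_resp] = [
        2.0 * np.pi * l * fr for l in range(1, config.n_resp + 1)
    ]
    rates[config.n_cardiac + config.n_resp :] = [
        2.0 * np.pi * (k * fc + s * l * fr) for k, l, s in config.mod_pairs
    ]
    return rates


def nam_transition(
    x: np.ndarray, config: HarmonicConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One-step state propagation and its exact Jacobian.

    Offset, amplitudes and base frequencies are random walks (identity
    rows); phases advance by their instantaneous rate times Δt.  The
    Jacobian is the identity plus the 2π·multiplier·Δt couplings from the
    frequency states into the phase rows.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (config.dim,):
        raise ValueError("state length does not match config layout")
    dt = config.dt
    out = x.copy()
    out[config.sl_phases] = x[config.sl_phases] + _phase_rates(x, config) * dt

    A = np.eye(config.dim)
    phase0 = config.sl_phases.start
    # ∂θ/∂f couplings
    for j, k in enumerate(range(1, config.n_cardiac + 1)):
        A[phase0 + j, config.idx_fc] = 2.0 * np.pi * k * dt
    for j, l in enumerate(range(1, config.n_resp + 1)):
        A[phase0 + config.n_cardiac + j, config.idx_fr] = 2.0 * np.pi * l * dt
    for j, (k, l, s) in enumerate(config.mod_pairs):
        row = phase0 + config.n_cardiac + config.n_resp + j
        A[row, config.idx_fc] = 2.0 * np.pi * k * dt
        A[row, config.idx_fr] = 2.0 * np.pi * s * l * dt
    return out, A


def nam_measure(x: np.ndarray, config: HarmonicConfig) -> float:
    """h(x) = c + Σ a·cos θ over all cardiac, respiratory and modulation terms."""
    x = np.asarray(x, dtype=float)
    amps = x[config.sl_amplitudes]
    phases = x[config.sl_phases]
    return float(x[config.idx_offset] + amps @ np.cos(phases))


def nam_measurement_jacobian(x: np.ndarray, config: HarmonicConfig) -> np.ndarray:
    """Row vector ∂h/∂x: 1 for the offset, cos θ per amplitude, −a·sin θ per
    phase, 0 for the frequency states (they act only through the phase
    dynamics)."""
    x = np.asarray(x, dtype=float)
    H = np.zeros(config.dim)
    H[config.idx_offset] = 1.0
    amps = x[config.sl_amplitudes]
    phases = x[config.sl_phases]
    H[config.sl_amplitudes] = np.cos(phases)
    H[config.sl_phases] = -amps * np.sin(phases)
    return H


def wrap_phase(theta: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]; cos is 2π-periodic so the measurement is unchanged."""
    wrapped = -((-np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


def nam_ekf_step(
    belief: GaussianBelief,
    z: float,
    config: HarmonicConfig,
    noise: NamNoise,
) -> tuple[GaussianBelief, Innovation]:
    """One EKF cycle: nonlinear predict, linearized update, phase wrap.

    Base frequencies are clamped to the positivity floor and phases wrapped
    to (−π, π] after the update; the covariance is untouched by either.
    """
    if belief.dim != config.dim:
        raise ValueError("belief dimension does not match config layout")
    mean, A = nam_transition(belief.mean, config)
    P = symmetrize(A @ belief.covariance @ A.T + np.diag(noise.diagonal(config)))
    prior = GaussianBelief(mean, P)
    residual = float(z) - nam_measure(mean, config)
    H = nam_measurement_jacobian(mean, config)
    post, innov = update_with_residual(
        prior, np.array([residual]), H[None, :], np.array([[noise.r_meas]]),
        mode_name="NAM",
    )
    g = noise.gate_sigma
    S = innov.covariance[0, 0]
    if g > 0 and residual * residual > g * g * S:
        # robust update: inflate R so the standardized residual equals the
        # gate, then redo the update with the reduced gain
        HPH = S - noise.r_meas
        r_infl = residual * residual / (g * g) - HPH
        post, _ = update_with_residual(
            prior, np.array([residual]), H[None, :], np.array([[r_infl]]),
            mode_name="NAM",
        )
    # physiological-range projections: base frequencies stay inside their
    # bands (generalizing the positivity floor), amplitudes inside the
    # data-scale bound; covariance untouched, as for phase wrapping
    post.mean[config.idx_fc] = float(
        np.clip(post.mean[config.idx_fc], *CARDIAC_BAND)
    )
    post.mean[config.idx_fr] = float(np.clip(post.mean[config.idx_fr], *RESP_BAND))
    if np.isfinite(noise.amp_limit):
        sl = config.sl_amplitudes
        post.mean[sl] = np.clip(post.mean[sl], -noise.amp_limit, noise.amp_limit)
    post.mean[config.sl_phases] = wrap_phase(post.mean[config.sl_phases])
    return post, innov


# ---------------------------------------------------------------------------
# initialization from data
# ---------------------------------------------------------------------------

def _band_peak(freqs: np.ndarray, power: np.ndarray, band: tuple[float, float],
               label: str) -> float:
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise InitializationError(
            f"no spectral support in the {label} band {band}; "
            "supply frequencies explicitly"
        )
    bf, bp = freqs[mask], power[mask]
    i = int(np.argmax(bp))
    floor = max(float(np.median(bp)), 1e-300)
    if bp[i] <= 1e-12 or bp[i] < 5.0 * floor:
        raise InitializationError(
            f"no dominant spectral peak in the {label} band {band}; "
            "supply frequencies explicitly"
        )
    # parabolic interpolation around the peak bin
    f0 = bf[i]
    if 0 < i < len(bf) - 1:
        y0, y1, y2 = np.log(bp[i - 1] + 1e-300), np.log(bp[i] + 1e-300), np.log(
            bp[i + 1] + 1e-300
        )
        denom = y0 - 2.0 * y1 + y2
        if abs(denom) > 1e-12:
            shift = 0.5 * (y0 - y2) / denom
            f0 = bf[i] + np.clip(shift, -1.0, 1.0) * (bf[1] - bf[0])
    return float(f0)


def _dictionary_residual(t, y, freqs) -> float:
    """LS residual of projecting y onto constant + cos/sin at ``freqs``."""
    cols = [np.ones_like(t)]
    for f in freqs:
        w = 2 * np.pi * f * t
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    X = np.column_stack(cols)
    beta, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    r = y - X @ beta
    return float(r @ r)


def _refine_fundamental(t, y, band, freqs_for, coarse_step=0.01) -> float:
    """Pick the fundamental minimizing the full-dictionary fit residual.

    A short window gives the periodogram too little resolution to separate
    a slow fundamental from its own harmonics, so the scan evaluates the
    *whole* implied dictionary (``freqs_for(f)``) at each candidate over
    the band and then polishes the winner with a bounded search.
    """
    lo, hi = band
    candidates = np.arange(lo, hi + coarse_step / 2, coarse_step)
    costs = [_dictionary_residual(t, y, freqs_for(f)) for f in candidates]
    f0 = float(candidates[int(np.argmin(costs))])
    res = optimize.minimize_scalar(
        lambda f: _dictionary_residual(t, y, freqs_for(f)),
        bounds=(max(f0 - coarse_step, lo), min(f0 + coarse_step, hi)),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x)


def _component_frequencies(config: HarmonicConfig, fc: float, fr: float):
    """All dictionary frequencies in state order (after the offset)."""
    freqs = [k * fc for k in range(1, config.n_cardiac + 1)]
    freqs += [l * fr for l in range(1, config.n_resp + 1)]
    freqs += [k * fc + s * l * fr for k, l, s in config.mod_pairs]
    return np.asarray(freqs)


def nam_init_from_signal(
    signal: SignalTrace | np.ndarray,
    config: HarmonicConfig,
    sample_rate: float | None = None,
    f_cardiac: float | None = None,
    f_resp: float | None = None,
) -> GaussianBelief:
    """Initialize the harmonic state from a short stretch of data.

    The two base frequencies are located as the dominant periodogram peaks
    in the cardiac (0.6-3.5 Hz) and respiratory (0.05-0.6 Hz) bands and
    refined by a local least-squares fit; amplitudes and phases then come
    from projecting the data onto the implied cosine dictionary.  The
    returned belief is anchored at the time of the *last* sample, so the
    first EKF predict advances it to the next one.  Raises
    :class:`InitializationError` when a band holds no dominant peak.
    """
    if isinstance(signal, SignalTrace):
        y = signal.channel(0).astype(float)
        fs = signal.sample_rate
    else:
        y = np.asarray(signal, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        fs = float(sample_rate)
    n = y.shape[0]
    t = np.arange(n) / fs
    yc = y - y.mean()

    freqs, power = sp_signal.periodogram(yc, fs)
    if f_cardiac is None:
        if config.n_cardiac > 0:
            # the band peak is only a sanity gate; the estimate itself comes
            # from scanning the harmonic dictionary over the band
            _band_peak(freqs, power, CARDIAC_BAND, "cardiac")
            ks = range(1, config.n_cardiac + 1)
            f_cardiac = _refine_fundamental(
                t, yc, CARDIAC_BAND, lambda f: [k * f for k in ks],
                coarse_step=0.02,
            )
        else:
            f_cardiac = 1.0
    if f_resp is None:
        if config.n_resp > 0:
            try:
                _band_peak(freqs, power, RESP_BAND, "respiratory")
            except InitializationError:
                # respiration may be genuinely absent; keep a nominal rate
                f_resp = 0.25
            else:
                fc = f_cardiac
                f_resp = _refine_fundamental(
                    t, yc, RESP_BAND,
                    lambda f: _component_frequencies(config, fc, f),
                    coarse_step=0.01,
                )
        else:
            f_resp = 0.25

    comp_freqs = _component_frequencies(config, f_cardiac, f_resp)
    cols = [np.ones(n)]
    for f in comp_freqs:
        cols.append(np.cos(2 * np.pi * f * t))
        cols.append(np.sin(2 * np.pi * f * t))
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)

    mean = np.zeros(config.dim)
    mean[config.idx_offset] = beta[0]
    n_comp = len(comp_freqs)
    alphas = beta[1 : 1 + 2 * n_comp : 2]
    betas = beta[2 : 2 + 2 * n_comp : 2]
    # a cos(2πft + φ) = α cos(2πft) + β sin(2πft) with α = a cos φ, β = −a sin φ
    amps = np.hypot(alphas, betas)
    phis = np.arctan2(-betas, alphas)
    mean[config.sl_amplitudes] = amps
    mean[config.idx_fc] = f_cardiac
    mean[config.idx_fr] = f_resp
    t_anchor = t[-1]
    mean[config.sl_phases] = wrap_phase(2 * np.pi * comp_freqs * t_anchor + phis)

    scale = max(float(np.std(yc)), 1e-3)
    var = np.empty(config.dim)
    var[config.idx_offset] = (0.2 * scale) ** 2
    var[config.sl_amplitudes] = (0.2 * scale) ** 2
    var[config.idx_fc] = 0.05**2
    var[config.idx_fr] = 0.05**2
    var[config.sl_phases] = 0.2**2
    return GaussianBelief(mean, np.diag(var))


# ---------------------------------------------------------------------------
# online predictor
# ---------------------------------------------------------------------------

class NamPredictor:
    """Sequential one-/multi-step predictor wrapping the harmonic EKF.

    Implements the common online protocol used by the evaluation harness
    and the fusion bank: ``update(z)`` advances one sample and returns the
    one-step-ahead (prior) prediction made for it; ``forecast(h)``
    extrapolates ``h`` samples ahead without mutating the filter.
    """

    name = "NAM"
    family = "nam"

    #: EW-averaged standardized squared innovation above this level marks
    #: degraded tracking (a healthy, well-calibrated filter sits below 1;
    #: re-acquiring from clean data is near-lossless, so the trigger is
    #: deliberately cheap)
    REINIT_THRESHOLD = 1.3
    #: seconds of recent data used for spectral re-acquisition
    REINIT_WINDOW_S = 8.0

    def __init__(self, config: HarmonicConfig, noise: NamNoise,
                 belief: GaussianBelief, reinit: bool = True):
        self.config = config
        self.noise = noise
        self.belief = belief
        self.reinit = reinit
        n_buf = int(round(self.REINIT_WINDOW_S / config.dt)) if config.dt > 0 else 0
        self._n_buf = n_buf
        self._buffer: list[float] = []
        self._misfit = 1.0
        self._since_reinit = 0

    @classmethod
    def from_signal(cls, signal, config: HarmonicConfig, noise: NamNoise,
                    sample_rate: float | None = None, **freq_kwargs):
        belief = nam_init_from_signal(
            signal, config, sample_rate=sample_rate, **freq_kwargs
        )
        return cls(config, noise, belief)

    # -- protocol -------------------------------------------------------
    def predicted_measurement(self) -> tuple[float, float]:
        """Filtered measurement estimate h(x̂) and its variance H P Hᵀ."""
        H = nam_measurement_jacobian(self.belief.mean, self.config)
        zhat = nam_measure(self.belief.mean, self.config)
        var = float(H @ self.belief.covariance @ H)
        return zhat, var

    def forecast(self, horizon: int) -> list[tuple[float, float]]:
        mean = self.belief.mean.copy()
        P = self.belief.covariance.copy()
        Q = np.diag(self.noise.diagonal(self.config))
        out = []
        for _ in range(horizon):
            mean, A = nam_transition(mean, self.config)
            P = symmetrize(A @ P @ A.T + Q)
            H = nam_measurement_jacobian(mean, self.config)
            out.append(
                (
                    nam_measure(mean, self.config),
                    float(H @ P @ H) + self.noise.r_meas,
                )
            )
        return out

    def update(self, z: float):
        """Advance one sample; returns (prior prediction, prior variance,
        innovation).

        A persistently large standardized innovation (track loss after an
        arrhythmic stretch) triggers spectral re-acquisition of the whole
        harmonic state from the recent sample buffer; predictions remain
        strictly causal.
        """
        prior_mean, _ = nam_transition(self.belief.mean, self.config)
        zpred = nam_measure(prior_mean, self.config)
        post, innov = nam_ekf_step(self.belief, z, self.config, self.noise)
        var = float(innov.covariance[0, 0])
        self.belief = post
        if self.reinit and self._n_buf > 0:
            self._track_health(float(z), innov)
        return zpred, var, innov

    def _track_health(self, z: float, innov: Innovation) -> None:
        self._buffer.append(z)
        if len(self._buffer) > self._n_buf:
            del self._buffer[: len(self._buffer) - self._n_buf]
        self._since_reinit += 1
        z2 = float(innov.residual[0] ** 2 / innov.covariance[0, 0])
        alpha = self.config.dt  # ~1 s time constant
        self._misfit += alpha * (min(z2, 100.0) - self._misfit)
        if (
            self._misfit > self.REINIT_THRESHOLD
            and len(self._buffer) == self._n_buf
            and self._since_reinit >= self._n_buf // 2
        ):
            try:
                self.belief = nam_init_from_signal(
                    np.asarray(self._buffer), self.config,
                    sample_rate=1.0 / self.config.dt,
                )
            except InitializationError:
                pass  # no usable spectrum yet; try again later
            self._misfit = 1.0
            self._since_reinit = 0

    @property
    def dt(self) -> float:
        return self.config.dt

    # -- fusion hooks ---------------------------------------------------
    def reacquire_hint(self) -> None:
        """Mark the track as lost so the next eligible step re-acquires the
        harmonic state from the recent buffer (used by the fusion bank when
        this mode's probability has collapsed)."""
        self._misfit = max(self._misfit, 10.0)

    def apply_anchor(self, delta: float, extra_var: float) -> None:
        """Re-anchor the offset state by the bank's measurement-space
        disagreement and inflate its variance by the spread term."""
        i = self.config.idx_offset
        self.belief.mean[i] += delta
        self.belief.covariance[i, i] += extra_var

    def clone(self) -> "NamPredictor":
        other = NamPredictor(self.config, self.noise, self.belief.copy(),
                             reinit=self.reinit)
        other._buffer = list(self._buffer)
        other._misfit = self._misfit
        other._since_reinit = self._since_reinit
        return other
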