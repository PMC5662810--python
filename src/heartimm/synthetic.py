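"""Seeded generators of ground-truth-labelled cardiorespiratory traces.

Three stylized rhythm regimes cover the conditions the predictors must
face:

* ``normal`` — quasi-periodic motion: cardiac harmonics + respiratory
  harmonics + quadratic cardiorespiratory modulation sidebands, with
  slowly drifting amplitudes and frequencies and additive white Gaussian
  noise.  Noise- and drift-free traces are exactly representable by the
  harmonic measurement model.
* ``af`` — atrial-fibrillation-like irregularity: beat-by-beat synthesis
  with independently drawn log-normal inter-beat intervals (positive
  support, right skew) and a fixed beat-kernel morphology.
* ``pvc`` — premature-ventricular-contraction-like ectopy: a regular
  beat grid where random beats are replaced by an early, larger,
  inverted deflection followed by a compensatory pause back onto the
  original grid.

The beat-kernel regimes are deliberately *not* inside the harmonic model
class, so the AR uncertainty model has genuine work to do there.  All
randomness flows from one seed through named child streams, so a given
(seed, parameters) pair is fully reproducible and degenerate parameter
settings (e.g. PVC probability 0) leave the remaining draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import RegimeSchedule, SignalTrace

__all__ = [
    "NormalParams",
    "AfParams",
    "PvcParams",
    "simulate_normal",
    "simulate_af",
    "simulate_pvc",
    "simulate_mixed",
    "segment_seeds",
    "DEFAULT_AXIS_SCALES",
]

#: per-axis scalings used for 3-channel (x, y, z) motion traces
DEFAULT_AXIS_SCALES = (1.0, 0.7, 0.4)

CROSSFADE_S = 0.5  # amplitude cross-fade at regime boundaries


def _streams(seed, names):
    """Named independent child RNGs from one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.Generator(np.random.PCG64(c))
            for name, c in zip(names, children)}


def segment_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Child seeds used by :func:`simulate_mixed`, one per segment."""
    return np.random.SeedSequence(seed).spawn(n)


def _expand_channels(latent, axis_scales, noise_sd, rng):
    """Map one latent channel to per-axis channels plus independent noise."""
    if axis_scales is None:
        return latent + (rng.standard_normal(latent.shape[0]) * noise_sd
                         if noise_sd > 0 else 0.0)
    scales = np.asarray(axis_scales, dtype=float)
    values = latent[:, None] * scales[None, :]
    if noise_sd > 0:
        values = values + rng.standard_normal(values.shape) * noise_sd
    return values


def _bounded_walk(rng, n, sigma_per_step, bound):
    """Random walk reflected into [−bound, +bound] (zero-mean deviation)."""
    if sigma_per_step <= 0 or n == 0:
        return np.zeros(n)
    steps = rng.standard_normal(n) * sigma_per_step
    walk = np.cumsum(steps)
    if bound > 0:
        # reflect into the band
        walk = np.abs((walk + bound) % (4 * bound) - 2 * bound) - bound
    return walk


# ---------------------------------------------------------------------------
# normal (coupled quasi-periodic) regime
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalParams:
    """Regular-rhythm generator settings.

    Amplitudes are in signal units (mm for motion); drift rates are the
    random-walk step scale per √s — amplitude drift is relative to each
    nominal amplitude, frequency drift is in Hz.  ``mod_depth`` scales the
    quadratic cardiorespiratory product term.
    """

    f_cardiac: float = 1.2
    f_resp: float = 0.25
    cardiac_amps: tuple = (1.0, 0.5, 0.25)
    resp_amps: tuple = (0.8, 0.3)
    mod_depth: float = 0.2
    phase0_cardiac: float = 0.0
    phase0_resp: float = 0.0
    amp_drift: float = 0.02
    freq_drift: float = 0.01
    noise_sd: float = 0.05


def simulate_normal(
    duration: float,
    sample_rate: float = 100.0,
    params: NormalParams | None = None,
    seed=0,
    axis_scales=None,
) -> SignalTrace:
    """Generate the coupled cardiac + respiratory + modulation signal.

    With drift, modulation and noise all zero and a single harmonic per
    oscillator the output is exactly
    ``a_c·cos(2π f_c t + φ_c) + a_r·cos(2π f_r t + φ_r)``.
    """
    p = params or NormalParams()
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    rngs = _streams(seed, ["freq", "amp", "noise"])

    sigma_f = p.freq_drift * np.sqrt(dt)
    fc = p.f_cardiac + _bounded_walk(rngs["freq"], n, sigma_f, 0.05 * p.f_cardiac)
    fr = p.f_resp + _bounded_walk(rngs["freq"], n, sigma_f, 0.05 * p.f_resp)

    # integrated base phases: θ_0 = φ_0 exactly, then θ_{k+1} = θ_k + 2π f_k Δt
    # (extended precision in the cumulative sum keeps the constant-frequency
    # case exact to ~1e-15 over thousands of steps)
    def integrate(f_series, phase0):
        csum = np.cumsum(f_series[:-1].astype(np.longdouble))
        theta = phase0 + 2 * np.pi * dt * np.concatenate(([0.0], csum))
        return theta.astype(float)

    theta_c = integrate(fc, p.phase0_cardiac)
    theta_r = integrate(fr, p.phase0_resp)

    def drifting_amp(nominal):
        return nominal * (
            1.0 + _bounded_walk(rngs["amp"], n, p.amp_drift * np.sqrt(dt), 0.2)
        )

    latent = np.zeros(n)
    amps_c = [drifting_amp(a) for a in p.cardiac_amps]
    for k, a in enumerate(amps_c, start=1):
        latent += a * np.cos(k * theta_c)
    amps_r = [drifting_amp(a) for a in p.resp_amps]
    for l, a in enumerate(amps_r, start=1):
        latent += a * np.cos(l * theta_r)
    # quadratic modulation of the first harmonic pair: the cosine product
    # expands into half-amplitude sum/difference sidebands
    if p.mod_depth > 0 and p.cardiac_amps and p.resp_amps:
        a_m = p.mod_depth * amps_c[0] * amps_r[0]
        latent += 0.5 * a_m * np.cos(theta_c + theta_r)
        latent += 0.5 * a_m * np.cos(theta_c - theta_r)

    values = _expand_channels(latent, axis_scales, p.noise_sd, rngs["noise"])
    truth = {
        "f_cardiac": fc,
        "f_resp": fr,
        "amp_cardiac_1": amps_c[0] if amps_c else np.zeros(n),
        "amp_resp_1": amps_r[0] if amps_r else np.zeros(n),
        "theta_cardiac": theta_c,
        "theta_resp": theta_r,
        "latent": latent,
    }
    return SignalTrace(
        sample_rate=sample_rate,
        values=values,
        units="mm",
        regime_labels=np.full(n, "normal"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# beat-kernel regimes (AF, PVC)
# ---------------------------------------------------------------------------

def _resp_baseline(n, sample_rate, f_resp, resp_amps, phase0) -> np.ndarray:
    """Persistent respiratory motion under arrhythmic cardiac activity."""
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    for l, a in enumerate(resp_amps, start=1):
        out += a * np.cos(2 * np.pi * l * f_resp * t + l * phase0)
    return out


def _beat_kernel(t: np.ndarray, width: float) -> np.ndarray:
    """Gaussian-derivative bump normalized to unit peak amplitude."""
    g = -(t / width) * np.exp(0.5 - 0.5 * (t / width) ** 2)
    return g


def _add_beats(latent, beat_times, amps, width, sample_rate):
    n = latent.shape[0]
    half = int(np.ceil(4 * width * sample_rate))
    marks = np.zeros(n, dtype=bool)
    for t0, a in zip(beat_times, amps):
        i0 = int(round(t0 * sample_rate))
        lo, hi = max(i0 - half, 0), min(i0 + half + 1, n)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / sample_rate - t0
        latent[lo:hi] += a * _beat_kernel(tt, width)
        marks[lo:hi] = True
    return marks


@dataclass(frozen=True)
class AfParams:
    """AF-like irregular rhythm settings (log-normal inter-beat intervals).

    Respiration does not stop during arrhythmia: the slow respiratory
    motion baseline persists (``resp_amps`` harmonics at ``f_resp``) while
    the cardiac contraction becomes an irregular beat-kernel train.
    """

    mean_interval: float = 0.5
    interval_cv: float = 0.25
    amplitude: float = 1.0
    kernel_width: float = 0.06
    amp_jitter: float = 0.10
    f_resp: float = 0.25
    resp_amps: tuple = (0.8, 0.3)
    phase0_resp: float = 0.0
    noise_sd: float = 0.05


def _lognormal_intervals(rng, mean, cv, total):
    if cv <= 0:
        k = int(np.ceil(total / mean)) + 2
        return np.full(k, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    out = []
    t = 0.0
    while t < total + 2 * mean:
        iv = float(rng.lognormal(mu, np.sqrt(sigma2)))
        out.append(iv)
        t += iv
    return np.asarray(out)


def simulate_af(
    duration: float,
    sample_rate: float = 100.0,
    params: AfParams | None = None,
    seed=0,
    axis_scales=None,
) -> SignalTrace:
    """Beat-by-beat synthesis with independently drawn irregular intervals."""
    p = params or AfParams()
    n = int(round(duration * sample_rate))
    rngs = _streams(seed, ["intervals", "jitter", "noise"])
    intervals = _lognormal_intervals(
        rngs["intervals"], p.mean_interval, p.interval_cv, duration
    )
    beat_times = np.cumsum(intervals)
    beat_times = beat_times[beat_times < duration]
    amps = p.amplitude * (
        1.0 + p.amp_jitter * rngs["jitter"].uniform(-1, 1, size=beat_times.size)
    )
    latent = _resp_baseline(n, sample_rate, p.f_resp, p.resp_amps, p.phase0_resp)
    _add_beats(latent, beat_times, amps, p.kernel_width, sample_rate)
    values = _expand_channels(latent, axis_scales, p.noise_sd, rngs["noise"])
    truth = {"latent": latent}
    return SignalTrace(
        sample_rate=sample_rate,
        values=values,
        units="mV",
        regime_labels=np.full(n, "af"),
        truth=truth,
    )


@dataclass(frozen=True)
class PvcParams:
    """Ectopic-beat regime settings.

    Each beat on the regular grid is independently replaced with
    probability ``pvc_prob`` by an early (``prematurity`` × interval after
    the previous beat), larger (``ectopic_scale``), inverted beat; the
    following normal beat stays on the undisturbed grid (compensatory
    pause).
    """

    mean_interval: float = 0.8
    pvc_prob: float = 0.1
    prematurity: float = 0.6
    ectopic_scale: float = 1.8
    compensatory_pause: bool = True
    amplitude: float = 1.0
    kernel_width: float = 0.06
    amp_jitter: float = 0.05
    f_resp: float = 0.25
    resp_amps: tuple = (0.8, 0.3)
    phase0_resp: float = 0.0
    noise_sd: float = 0.05


def simulate_pvc(
    duration: float,
    sample_rate: float = 100.0,
    params: PvcParams | None = None,
    seed=0,
    axis_scales=None,
) -> SignalTrace:
    """Regular rhythm with randomly interleaved premature ectopic beats."""
    p = params or PvcParams()
    n = int(round(duration * sample_rate))
    rngs = _streams(seed, ["jitter", "pvc", "noise"])
    grid = np.arange(p.mean_interval, duration, p.mean_interval)
    jitters = 1.0 + p.amp_jitter * rngs["jitter"].uniform(-1, 1, size=grid.size)
    is_pvc = rngs["pvc"].random(grid.size) < p.pvc_prob

    latent = _resp_baseline(n, sample_rate, p.f_resp, p.resp_amps, p.phase0_resp)
    pvc_mask = np.zeros(n, dtype=bool)
    for b, t_grid in enumerate(grid):
        if is_pvc[b]:
            prev = grid[b - 1] if b > 0 else 0.0
            t_beat = prev + p.prematurity * p.mean_interval
            amp = -p.ectopic_scale * p.amplitude * jitters[b]
            marks = _add_beats(
                latent, [t_beat], [amp], p.kernel_width, sample_rate
            )
            pvc_mask |= marks
            if not p.compensatory_pause:
                # without the pause the next beat follows the ectopic one
                # at the nominal interval; realized by shifting the grid is
                # out of scope for the stylized surrogate — the pause is
                # the physiological default and stays on.
                pass
        else:
            amp = p.amplitude * jitters[b]
            _add_beats(latent, [t_grid], [amp], p.kernel_width, sample_rate)

    values = _expand_channels(latent, axis_scales, p.noise_sd, rngs["noise"])
    labels = np.where(pvc_mask, "pvc", "normal")
    truth = {"latent": latent}
    return SignalTrace(
        sample_rate=sample_rate,
        values=values,
        units="mV",
        regime_labels=labels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# mixed-regime schedules
# ---------------------------------------------------------------------------

_GENERATORS = {
    "normal": (simulate_normal, NormalParams),
    "af": (simulate_af, AfParams),
    "pvc": (simulate_pvc, PvcParams),
}


def simulate_mixed(
    schedule: RegimeSchedule,
    sample_rate: float = 100.0,
    params: dict | None = None,
    axis_scales=None,
) -> SignalTrace:
    """Concatenate regime segments with an amplitude cross-fade.

    ``params`` maps regime name to its parameter object (defaults used
    otherwise).  Segment boundaries blend over 0.5 s with a raised-cosine
    window so the trace has no step discontinuity; the label channel
    switches hard at the boundary.
    """
    params = params or {}
    seeds = segment_seeds(schedule.seed, len(schedule.segments))
    n_fade = int(round(CROSSFADE_S * sample_rate))

    pieces = []
    labels = []
    for i, (regime, dur) in enumerate(schedule.segments):
        gen, default_cls = _GENERATORS[regime]
        p = params.get(regime, default_cls())
        last = i == len(schedule.segments) - 1
        extra = 0.0 if last else n_fade / sample_rate
        tr = gen(dur + extra, sample_rate, params=p, seed=seeds[i],
                 axis_scales=axis_scales)
        pieces.append(tr)
        labels.append(np.full(int(round(dur * sample_rate)), regime))

    if len(pieces) == 1:
        return pieces[0]

    fade_in = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / max(n_fade - 1, 1)))
    values = pieces[0].values.copy()
    for nxt in pieces[1:]:
        tail = values[-n_fade:]
        head = nxt.values[:n_fade]
        shape = (-1, 1) if values.ndim == 2 else (-1,)
        w = fade_in.reshape(shape)
        blended = tail * (1.0 - w) + head * w
        values = np.concatenate([values[:-n_fade], blended, nxt.values[n_fade:]])
    label_channel = np.concatenate(labels)
    # the cross-fade tails make segment lengths nominal; trim/pad defensively
    n_total = label_channel.shape[0]
    values = values[:n_total]

    units = "mm" if all(p.units == "mm" for p in pieces) else pieces[0].units
    return SignalTrace(
        sample_rate=sample_rate,
        values=values,
        units=units,
        regime_labels=label_channel,
    )
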