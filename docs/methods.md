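# Methods

`heartimm` predicts quasi-periodic beating-heart motion (or ECG-like
voltage) one or more samples ahead, under both regular rhythm and
arrhythmia, by running a bank of two dissimilar state-space models inside
an interacting-multiple-model (IMM) filter.

## The harmonic model (NAM)

Regular cardiorespiratory motion is modelled as

    x(t) = c + Σ_{k=1..N_c} a_k^c cos θ_k^c
             + Σ_{l=1..N_r} a_l^r cos θ_l^r
             + Σ_{k,l}      a_kl^m cos θ_kl^m ,

cardiac harmonics plus respiratory harmonics plus quadratic
cardiorespiratory modulation.  The modulation term is the product of the
cardiac and respiratory oscillations; expanding a product of cosines
gives sum- and difference-frequency sidebands, so the modulation
frequencies are *derived* as k·f^c ± l·f^r and are not free states (a
`sum_only` layout keeps a single sideband per (k, l) pair for the
literal one-term reading).  The state vector stacks the offset, all
amplitudes, the two base frequencies and all phases; offset, amplitudes
and frequencies evolve as random walks while phases integrate their
harmonic rate, θ̇_k = 2π·k·f.  The measurement is nonlinear in the
state, so an extended Kalman filter with the analytic Jacobians
(∂h/∂a = cos θ, ∂h/∂θ = −a sin θ, frequencies acting only through the
phase dynamics) tracks it.

Defaults: N_c = 3, N_r = 2, one modulated pair with both sidebands.
These match the harmonic content visible in the synthetic generator's
spectrum; on real data the counts should be read off the PSD.

### Numerical safeguards

EKF harmonic trackers have two well-known failure modes, both of which
appear when the observed rhythm leaves the model class (arrhythmia):

* **Amplitude runaway.**  A slow component with a nearly stationary
  phase is locally unidentifiable (a·cos θ ≈ const); persistent misfit
  can run its amplitude away with the offset compensating.  Amplitude
  states are clamped to ±5× the initialization-window SD; base
  frequencies are clamped into their spectral bands (cardiac
  0.6–3.5 Hz, respiratory 0.05–0.6 Hz), generalizing a simple
  positivity floor.  Clamps touch the mean only, never the covariance,
  like phase wrapping (phases are wrapped to (−π, π] after every
  update; cos is 2π-periodic so the measurement is unchanged).
* **False frequency lock.**  A phase-locked loop has a finite pull-in
  range: after an arrhythmic stretch drags the frequency states, the
  EKF can settle on a harmonic of the true rate and never return.  Two
  mechanisms address this.  (1) A Huber-style robust gate: when the
  standardized innovation exceeds 5σ, the measurement variance is
  inflated so the standardized residual sits at the gate — outliers get
  bounded influence.  The mode likelihood always uses the *ungated*
  innovation, so the fusion layer still sees honest misfit.  (2)
  Track-loss re-acquisition: an exponentially weighted average of the
  standardized squared innovation above 1.3 (a healthy filter sits
  below 1) triggers re-initialization from an 8-s rolling buffer of
  past samples, at most every 4 s.  Re-acquiring from clean data is
  nearly lossless, so the trigger is deliberately cheap.  Inside the
  fusion bank there is a third signal: a mode whose posterior
  probability stays below 0.2 for 2 s is hinted to re-acquire.  All
  three use only past data; predictions remain strictly causal.

### Initialization

The two base frequencies are estimated from a short window (the 10-s
tuning window by default).  A raw periodogram peak is only a sanity
gate: at 10 s the resolution (0.1 Hz) cannot separate a 0.25 Hz
respiratory fundamental from its own harmonics, and a false respiratory
lock poisons every other state.  Instead, each fundamental is chosen by
a coarse scan over its band that evaluates the least-squares residual
of the *entire* cosine dictionary implied by that fundamental, followed
by a bounded 1-d polish.  Amplitudes and phases then come from the
least-squares projection onto the dictionary; the belief is anchored at
the window's last sample with a broad diagonal covariance.  A constant
or peak-free signal raises an initialization error asking for explicit
frequencies.

## The AR uncertainty model (UIM)

Arrhythmic motion is not explained, only followed: an AR(p) model

    y_k = A_1 y_{k−1} + … + A_p y_{k−p} + v_k

in companion state-space form (coefficients in the first transition
row, identity subdiagonal, noise and observation on the first
component), tracked by a Kalman filter.  Orders 8 and 12 are the stock
variants (UIM8/UIM12).  Coefficients are re-estimated every sample by
exponentially weighted recursive least squares with forgetting factor
λ = 1 − Δt/T_resp (T_resp = 4 s), i.e. a memory horizon of one
respiratory period; the inverse-correlation matrix starts at δ·I with
δ = 10³.  An exponentially weighted running mean (same λ) is removed
before the regression and added back to predictions, since the AR model
is zero-mean.  Estimated coefficients are *not* stability-projected;
transient explosive estimates are tolerated and the KF stays well
defined.  The innovation variance is an EW average of squared RLS
residuals; `build_uim` inflates it by `q_scale` (default 10, the
deliberately loose choice for a wide-bandwidth standalone tracker).
Inside the fusion bank the evaluation harness pins `q_scale = 1`: the
filter's innovation covariance doubles as the bank's mode likelihood,
and a ×10 inflation flattens that likelihood enough to break regime
identification while leaving the filter's own RMS essentially unchanged.

## The fusion cycle (IMM)

A Markov chain with transition matrix p_ij switches between modes.
Each cycle: (1) mixing probabilities μ_{i|j} ∝ p_ij μ_i feed a
probability-weighted interaction; (2) each mode runs its own
predict/update; (3) the Gaussian innovation likelihood Λ_j re-weights
the predicted mode probabilities, μ_j ∝ μ_j(k+1|k) Λ_j, computed in the
log domain with max-subtraction so arrhythmic residuals cannot
underflow the whole bank; (4) the output is the probability-weighted
mixture of per-mode predictions with the mixture spread term added to
the variance.

The harmonic and AR state spaces differ in dimension and meaning, so
the textbook full-state mixing is undefined across families.  The
default cross-family converter is **output-level re-anchoring**: the
mixing column's blend of per-mode *measurement* predictions shifts the
receiving mode's offset (harmonic model) or most-recent-sample (AR
model) state component, and the measurement-space spread term inflates
that component's variance.  Same-family, same-dimension banks use full
state mixing; `probabilities_only` disables state interaction entirely
(an autonomous multiple-model bank) for ablation.

Switching probabilities come from expected sojourn times,
p_ii = 1 − 1/τ_i with the leave mass spread uniformly (defaults: 30 s
regular, 5 s irregular); the initial mode probabilities default to
(0.9, 0.1) for a regular-rhythm start.  A hook for signal-quality-driven
adaptation of the off-diagonal rates exists but ships disabled, since no
concrete scoring function is defined.

## Synthetic data

The generator produces labelled surrogates of three regimes:

* **normal** — the harmonic model's own signal class: cardiac harmonics
  (1.2 Hz; amplitudes 1.0/0.5/0.25 mm), respiratory harmonics (0.25 Hz;
  0.8/0.3 mm), product-term sidebands at f_c ± f_r (depth 0.2), with
  bounded random-walk drift of amplitudes (±20%, rate 0.02/√s) and
  frequencies (±5%, 0.01 Hz/√s), plus white Gaussian noise
  (SD 0.05 mm, sensor-grade for mm-scale motion).
* **af** — beat-by-beat synthesis with log-normal inter-beat intervals
  (mean 0.5 s, CV 0.25; positive support and right skew), a fixed
  Gaussian-derivative beat kernel with ±10% amplitude jitter.  The
  respiratory baseline persists: breathing does not stop during
  arrhythmia, only cardiac contraction becomes irregular.
* **pvc** — a regular beat grid (0.8 s) where each beat is independently
  replaced (default probability 0.1) by an early (60% of the interval),
  larger (×1.8), inverted beat followed by a compensatory pause back
  onto the undisturbed grid.

The beat-kernel regimes are deliberately outside the harmonic model
class so the AR model has genuine work to do.  Mixed schedules
concatenate segments with a 0.5-s raised-cosine cross-fade; labels
switch hard at the boundary.  All randomness flows from one seed
through named child streams (PCG64), so traces are bit-reproducible and
degenerate settings (PVC probability 0) leave the other draws
untouched.  Three-channel (x, y, z) motion applies per-axis scalings
(1.0/0.7/0.4) to one latent channel with independent per-axis noise —
there is no cross-axis dynamic model, and filtering is per-axis.

What the surrogates do *not* emulate: real electrophysiology (no
P-QRS-T morphology model), respiration mechanics, cross-axis coupling,
or the specific arrhythmia-like motion obtained by external stimulation
in animal experiments.  Passing results on these surrogates demonstrate
the machinery — regime switching, fusion benefit, robustness — not
clinical performance.

## Evaluation protocol

Each predictor is tuned by a coarse grid search minimizing one-step RMS
on the first 10 s of the record, then filters the remainder strictly
causally; every reported prediction for sample k uses data up to
k − horizon only, and the tuning window is excluded from scoring.  The
metric is χ = √(Σe²/n), summed over channels for 3-D motion.  Within
the tuning window, candidates are initialized from the first half and
scored on the second, so the search rewards tracking rather than
replaying the initialization.

The searched grids keep the noise *structure* fixed and search scalar
factors (a 10-s window cannot identify slow-drift parameters):
amplitude-block variance {1e-4, 3e-4}, phase-block {3e-5, 1e-4, 3e-4}
per step with the frequency block tied 1:1 to the phase block, and the
measurement variance at {0.5, 1, 2}× a second-difference noise estimate
(var(Δ²y)/6).  The AR side fixes λ by the respiratory-period rule and
does not search `q_scale` (one-step RMS is insensitive to it, which
makes an RMS-driven choice arbitrary).

`compare_all` runs NAM, UIM8, UIM12, IMM8 = {NAM, UIM8} and
IMM12 = {NAM, UIM12} under the identical protocol and reports RMS ± SD,
the SD taken across seeded noise realizations when a trace factory is
supplied (the provenance of a single-trace SD is otherwise undefined);
per-regime RMS columns appear when labels exist.  Horizons: 1 step
(default), with multi-step prediction available for middle (0.1 s) and
long (one beat period) scales.

Problem sizes used by the shipped checks: regular-rhythm traces 40 s
and mixed normal 30 s / AF 20 s / normal 30 s traces at 100 Hz, ten
seeds for the ordering comparisons; 5 000 samples for AR(8) coefficient
recovery; 100 000 fusion cycles for probability conservation.

## Numerical choices

Joseph-form covariance updates; Cholesky solves, never explicit
inverses; covariances re-symmetrized after every operation; likelihoods
kept in the log domain until the single normalization point.  A mixing
column whose predicted mode probability underflows (< 1e-30) is set
uniform with a warning; if every mode's likelihood underflows, the mode
probabilities keep their predicted values.  Ties in grid search keep
the first (smallest) candidate.

## Known limitations

* The harmonic model's recovery after long arrhythmic stretches relies
  on re-acquisition, not on EKF pull-in; with re-acquisition disabled
  (`reinit=False`) a false harmonic lock can persist indefinitely.
* Mode likelihoods are only as honest as each filter's innovation
  covariance; strongly inflated process noise in any member degrades
  regime identification (hence the bank's `q_scale = 1` policy).
* Multi-channel records are filtered per axis with shared tuning from
  the first channel; mode probabilities are reported for that channel.
* WFDB support covers format-16 single-file records only.
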