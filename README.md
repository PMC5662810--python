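# heartimm

Beating-heart motion prediction by interacting-multiple-model (IMM)
fusion of two dissimilar trackers.

Robot-assisted beating-heart surgery needs the heart's future position a
fraction of a second ahead so the instrument can move with it.  Regular
rhythm is quasi-periodic — cardiac harmonics, respiratory harmonics and
their quadratic coupling — and is tracked well by a harmonic state-space
model.  Arrhythmias (atrial fibrillation, premature ventricular
contractions) break that structure and are better followed by a
wide-bandwidth adaptive AR model.  `heartimm` runs both inside one IMM
filter bank that mixes their estimates, re-weights them every sample by
innovation likelihood, and switches regimes automatically.

The package is aimed at researchers in physiological signal processing
and motion compensation who want a reproducible, testable reference
implementation with a synthetic arrhythmia generator and a comparative
evaluation harness.

## Models

* **NAM** (nonlinear adaptive model): x(t) = c + Σₖ aₖᶜ cos θₖᶜ +
  Σₗ aₗʳ cos θₗʳ + Σₖₗ aₖₗᵐ cos θₖₗᵐ, with random-walk offset,
  amplitudes and base frequencies, phases advancing at 2π·k·f·Δt, and
  derived modulation frequencies k·f ᶜ ± l·f ʳ; tracked by an EKF with
  analytic Jacobians.
* **UIM8 / UIM12** (uncertainty irregular models): AR(p) in companion
  state-space form, p ∈ {8, 12}, coefficients re-estimated every sample
  by forgetting-factor RLS, process noise deliberately loose; tracked by
  a KF.
* **IMM8 / IMM12**: the two-mode banks {NAM, UIM8} and {NAM, UIM12}
  with sojourn-time switching probabilities p_ii = 1 − 1/τ_i and
  measurement-space combination ẑ = Σ μ_j ẑ_j,
  σ² = Σ μ_j [σ_j² + (ẑ_j − ẑ)²].

Prediction quality is scored with the RMS error
χ = √((e₁² + … + e_n²)/n), summed over axes for 3-D motion, after
tuning free noise parameters on the first 10 s of each record.

## Worked example

```python
from heartimm import synthetic, models
from heartimm.trace import RegimeSchedule

trace = synthetic.simulate_mixed(
    RegimeSchedule([("normal", 30.0), ("af", 20.0), ("normal", 30.0)], seed=11),
    sample_rate=100.0,
)
res = models.ImmModel(trace, bank="imm12").fit(horizon=1)
print(res.summary())
```

```
             Heart-motion prediction results
==========================================================
Predictor:            IMM12
Horizon (steps):      1
Sample rate (Hz):     100
Tuning window (s):    10
Scored samples:       7000
----------------------------------------------------------
RMS error:            0.0736192
  RMS [af]:           0.0882509
  RMS [normal]:       0.0668761
  mean mu[NAM]:       0.6640
  mean mu[UIM12]:     0.3360
----------------------------------------------------------
mixing:               output_anchor
mu0:                  (0.9, 0.1)
nam.q_amp:            0.0001
nam.q_freq:           3e-05
nam.q_phase:          3e-05
nam.r_meas:           0.005533824013396514
sojourn_s:            (30.0, 5.0)
uim.forgetting:       0.9975
uim.q_scale:          1.0
uim.r_meas:           0.002766912006698257
==========================================================
```

The trace is 80 s of labelled synthetic motion: 30 s regular rhythm,
20 s AF-like irregularity, 30 s regular again, with 0.05 mm measurement
noise.  The bank's one-step RMS (0.074 mm) sits near the best single
model in each regime: in the regular segments the harmonic model's
posterior probability is high and the error (0.067 mm) matches its
level; during AF the AR model takes over (hence mean μ[NAM] ≈ 0.66 over
the whole record) and the error stays at the AR level rather than the
harmonic model's much worse arrhythmic error.  `res.mode_probs` holds
the full per-sample posterior trajectory.

Single models work the same way: `models.NamModel(trace).fit()`,
`models.ArUncertaintyModel(trace, order=8).fit()`.  The five-way
comparison is one call:

```python
from heartimm import compare_all
table = compare_all(trace, horizon=1)
```

A command-line interface mirrors the library:

```sh
heartimm simulate --schedule normal:30,af:20,normal:30 --seed 7 -o trace.csv
heartimm predict trace.csv --predictor IMM12 -o predictions.csv
heartimm evaluate predictions.csv
heartimm compare trace.csv -o table.csv --meta-out meta.json
```

Traces are CSV (`time_s, ch1[, ch2, ch3][, regime]`); WFDB format-16
header+signal records are read directly, with channel selection by
description (e.g. `MLII`, `V1`).

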