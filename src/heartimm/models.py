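"""Model/Results front end in the spirit of statsmodels' time-series API.

Each model class is built from the observed series (an array or a
:class:`~heartimm.trace.SignalTrace`) plus its sampling rate; ``fit()``
tunes the free noise parameters on the leading window, filters the rest
causally and returns a :class:`PredictionResults` carrying the
predictions, errors, RMS, tuned parameters and — for the fusion bank —
the mode-probability trajectory, with a ``summary()`` table.

>>> from heartimm import synthetic, models
>>> trace = synthetic.simulate_normal(40, 100.0, seed=3)
>>> res = models.ImmModel(trace, bank="imm12").fit()
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from .evaluation import PredictionRun, run_predictor
from .trace import SignalTrace

__all__ = ["NamModel", "ArUncertaintyModel", "ImmModel", "PredictionResults"]


class PredictionResults:
    """Causal prediction results for one fitted predictor.

    Attributes
    ----------
    predictions, actuals, errors : ndarray
        Aligned over the scored (post-tuning-window) samples.
    params : dict
        The tuned hyperparameters.
    mode_probs : ndarray or None
        Per-sample posterior mode probabilities (fusion banks only).
    """

    def __init__(self, model, run: PredictionRun):
        self.model = model
        self._run = run
        self.predictions = run.predictions
        self.actuals = run.actuals
        self.errors = run.errors
        self.params = run.tuned_params
        self.mode_probs = run.mode_probs
        self.mode_names = run.mode_names
        self.horizon = run.horizon

    @property
    def rms(self) -> float:
        """Root-mean-square prediction error over the scored samples."""
        return self._run.rms

    def rms_by_regime(self) -> dict:
        return self._run.rms_by_regime()

    def mean_mode_probs(self) -> dict:
        if self.mode_probs is None:
            return {}
        means = np.nanmean(self.mode_probs, axis=0)
        return dict(zip(self.mode_names, means.tolist()))

    def summary(self) -> str:
        run = self._run
        width = 58
        lines = [
            "Heart-motion prediction results".center(width),
            "=" * width,
            f"{'Predictor:':<22}{run.predictor}",
            f"{'Horizon (steps):':<22}{run.horizon}",
            f"{'Sample rate (Hz):':<22}{run.sample_rate:g}",
            f"{'Tuning window (s):':<22}{run.tuning_seconds:g}",
            f"{'Scored samples:':<22}{len(run.errors)}",
            "-" * width,
            f"{'RMS error:':<22}{run.rms:.6g}",
        ]
        for regime, value in sorted(run.rms_by_regime().items()):
            lines.append(f"{'  RMS [' + regime + ']:':<22}{value:.6g}")
        for name, mu in self.mean_mode_probs().items():
            lines.append(f"{'  mean mu[' + name + ']:':<22}{mu:.4f}")
        lines.append("-" * width)
        for key, value in sorted(_flatten(self.params).items()):
            lines.append(f"{key + ':':<22}{value}")
        lines.append("=" * width)
        return "\n".join(lines)


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


class _BasePredictionModel:
    """Shared constructor: accept a trace or (array, sample_rate)."""

    _predictor_id = ""

    def __init__(self, endog, sample_rate: float | None = None):
        if isinstance(endog, SignalTrace):
            self.trace = endog
        else:
            if sample_rate is None:
                raise ValueError("sample_rate required for array input")
            self.trace = SignalTrace(
                sample_rate=float(sample_rate),
                values=np.asarray(endog, dtype=float),
            )

    @classmethod
    def from_trace(cls, trace: SignalTrace, **kwargs):
        return cls(trace, **kwargs)

    def _params(self) -> dict:
        return {}

    def fit(
        self,
        horizon: int = 1,
        tuning_seconds: float = 10.0,
        tune: bool = True,
    ) -> PredictionResults:
        """Tune on the leading window, filter the rest, score causally."""
        run = run_predictor(
            self.trace,
            self._predictor_id,
            horizon=horizon,
            tuning_seconds=tuning_seconds,
            params=self._params(),
            tune=tune,
        )
        return PredictionResults(self, run)


class NamModel(_BasePredictionModel):
    """Modulated-sinusoid harmonic model tracked by an EKF.

    Parameters beyond the series: harmonic counts (cardiac, respiratory,
    modulated) and the sideband layout of the quadratic coupling term.
    """

    _predictor_id = "NAM"

    def __init__(self, endog, sample_rate=None, n_cardiac=3, n_resp=2,
                 n_mod_cardiac=1, n_mod_resp=1,
                 sidebands="sum_and_difference"):
        super().__init__(endog, sample_rate)
        self.n_cardiac = n_cardiac
        self.n_resp = n_resp
        self.n_mod_cardiac = n_mod_cardiac
        self.n_mod_resp = n_mod_resp
        self.sidebands = sidebands

    def _params(self):
        return {
            "n_cardiac": self.n_cardiac,
            "n_resp": self.n_resp,
            "n_mod_cardiac": self.n_mod_cardiac,
            "n_mod_resp": self.n_mod_resp,
            "sidebands": self.sidebands,
        }


class ArUncertaintyModel(_BasePredictionModel):
    """Adaptive AR(p) companion-form Kalman predictor (UIM8 / UIM12)."""

    def __init__(self, endog, sample_rate=None, order=8):
        super().__init__(endog, sample_rate)
        if order not in (8, 12):
            # any order is mechanically fine; the stock bank uses 8 and 12
            raise ValueError("stock uncertainty models use order 8 or 12")
        self.order = order

    @property
    def _predictor_id(self):
        return f"UIM{self.order}"


class ImmModel(_BasePredictionModel):
    """Interacting-multiple-model bank {harmonic EKF, AR KF}.

    ``bank`` selects the AR member order: ``"imm8"`` or ``"imm12"``.
    ``mu0`` is the initial mode-probability guess, ``sojourn_s`` the
    expected dwell times (regular, irregular) in seconds that set the
    switching matrix, and ``mixing`` the state-interaction scheme
    (``output_anchor`` | ``probabilities_only``).
    """

    def __init__(self, endog, sample_rate=None, bank="imm12",
                 mu0=(0.9, 0.1), sojourn_s=(30.0, 5.0),
                 mixing="output_anchor"):
        super().__init__(endog, sample_rate)
        bank = bank.lower()
        if bank not in ("imm8", "imm12"):
            raise ValueError("bank must be 'imm8' or 'imm12'")
        self.bank = bank
        self.mu0 = tuple(mu0)
        self.sojourn_s = tuple(sojourn_s)
        self.mixing = mixing

    @property
    def _predictor_id(self):
        return self.bank.upper()

    def _params(self):
        return {
            "mu0": self.mu0,
            "sojourn_s": self.sojourn_s,
            "mixing": self.mixing,
        }
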