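"""Uniformly sampled signal container shared by the generators, readers and filters."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical regime label values
REGIMES = ("normal", "af", "pvc")


@dataclass
class SignalTrace:
    """A uniformly sampled single- or multi-channel signal.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (> 0).
    values : ndarray
        Shape ``(n,)`` for one channel or ``(n, n_ch)`` for several.
        Units are carried in ``units`` (e.g. ``"mm"`` for motion,
        ``"mV"`` for ECG-like voltage).
    channel_names : tuple of str
        One name per channel (defaults to ``ch1, ch2, ...``).
    units : str
        Physical unit of the sample values.
    regime_labels : ndarray of str, optional
        Per-sample rhythm regime, one of :data:`REGIMES`.
    truth : dict, optional
        Generator internals (instantaneous amplitudes / frequencies /
        phases) keyed by name, each an array of length ``n``.
    """

    sample_rate: float
    values: np.ndarray
    channel_names: tuple = ()
    units: str = "mm"
    regime_labels: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i + 1}" for i in range(self.n_channels)
            )
        if len(self.channel_names) != self.n_channels:
            raise ValueError("one channel name per channel required")
        if self.regime_labels is not None:
            self.regime_labels = np.asarray(self.regime_labels)
            if len(self.regime_labels) != self.n_samples:
                raise ValueError("regime_labels length must match values")
        for key, arr in self.truth.items():
            if len(np.asarray(arr)) != self.n_samples:
                raise ValueError(f"truth channel {key!r} has wrong length")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    # -- access ---------------------------------------------------------
    def channel(self, name_or_index) -> np.ndarray:
        """Return one channel as a 1-d array, selected by name or index."""
        if isinstance(name_or_index, str):
            if name_or_index not in self.channel_names:
                raise KeyError(
                    f"unknown channel {name_or_index!r}; "
                    f"available: {list(self.channel_names)}"
                )
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        if self.values.ndim == 1:
            if idx != 0:
                raise KeyError("trace has a single channel")
            return self.values
        return self.values[:, idx]

    def slice(self, start_s: float, stop_s: float | None = None) -> "SignalTrace":
        """Return the sub-trace from ``start_s`` (inclusive) to ``stop_s``."""
        i0 = int(round(start_s * self.sample_rate))
        i1 = self.n_samples if stop_s is None else int(round(stop_s * self.sample_rate))
        return replace(
            self,
            values=self.values[i0:i1],
            regime_labels=None if self.regime_labels is None else self.regime_labels[i0:i1],
            truth={k: np.asarray(v)[i0:i1] for k, v in self.truth.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with a ``time_s`` column, one column per channel
        and, when present, the ``regime`` label column."""
        data = {"time_s": self.times()}
        if self.values.ndim == 1:
            data[self.channel_names[0]] = self.values
        else:
            for i, name in enumerate(self.channel_names):
                data[name] = self.values[:, i]
        if self.regime_labels is not None:
            data["regime"] = self.regime_labels
        return pd.DataFrame(data)


@dataclass
class RegimeSchedule:
    """Ordered list of ``(regime, duration_s)`` segments with a global seed."""

    segments: list
    seed: int = 0

    def __post_init__(self):
        for regime, duration in self.segments:
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}")
            if duration <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    @classmethod
    def parse(cls, text: str, seed: int = 0) -> "RegimeSchedule":
        """Parse ``"normal:30,af:20,normal:30"`` into a schedule."""
        segments = []
        for part in text.split(","):
            regime, _, dur = part.strip().partition(":")
            segments.append((regime.strip(), float(dur)))
        return cls(segments, seed=seed)
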