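"""Trace readers/writers and run configuration.

CSV is the canonical interchange format: a header row with ``time_s``,
one column per channel, and an optional ``regime`` label column.  WFDB
header + signal record pairs (the layout used by the MIT-BIH arrhythmia
database and PhysioNet generally) are supported read-only for the
16-bit sample format, with ADC-to-physical conversion per the header
gain/baseline and channel selection by description (``"MLII"``,
``"V1"``, ...).  A matching writer exists so round trips can be tested
without shipping data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import SignalTrace

__all__ = [
    "FormatError",
    "read_trace",
    "write_trace",
    "read_wfdb",
    "write_wfdb",
    "load_config",
    "save_config",
]

logger = logging.getLogger(__name__)

TIME_JITTER_TOL = 1e-6  # relative jitter tolerated in the time column


class FormatError(ValueError):
    """Input file violates the expected on-disk layout."""


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_trace(trace: SignalTrace, path) -> None:
    """Write ``time_s, ch..., [regime]`` CSV.

    Units are metadata, not data: they travel in configs and reports
    rather than in a comment row that many CSV readers would choke on.
    """
    trace.to_frame().to_csv(path, index=False, float_format="%.12g")


def _read_csv(path, channel=None) -> SignalTrace:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise FormatError(f"{path}: time_s must be strictly increasing")
    jitter = float(np.max(np.abs(dt - dt0))) / dt0
    if jitter > 1e-3:
        raise FormatError(
            f"{path}: non-uniform sampling (relative jitter {jitter:.2g})"
        )
    if jitter > TIME_JITTER_TOL:
        logger.warning(
            "%s: time jitter %.2g above tolerance; resampling onto the "
            "nominal grid", path, jitter,
        )
    sample_rate = 1.0 / dt0

    regimes = None
    if "regime" in df.columns:
        regimes = df["regime"].to_numpy(dtype=str)
    channels = [c for c in df.columns if c not in ("time_s", "regime")]
    if not channels:
        raise FormatError(f"{path}: no signal channels found")
    if channel is not None:
        if channel not in channels:
            raise FormatError(
                f"{path}: unknown channel {channel!r}; available: {channels}"
            )
        channels = [channel]
    values = df[channels].to_numpy(dtype=float)
    if values.shape[1] == 1:
        values = values[:, 0]
    return SignalTrace(
        sample_rate=sample_rate,
        values=values,
        channel_names=tuple(channels),
        regime_labels=regimes,
    )


# ---------------------------------------------------------------------------
# WFDB (format 16 only)
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    rec = lines[0].split()
    if len(rec) < 3:
        raise FormatError(
            f"{hea_path}: malformed record line 1: {lines[0]!r}"
        )
    name = rec[0].split("/")[0]
    try:
        n_sig = int(rec[1])
        fs = float(rec[2].split("/")[0])
        n_samples = int(rec[3]) if len(rec) > 3 else 0
    except ValueError as exc:
        raise FormatError(
            f"{hea_path}: malformed record line 1: {lines[0]!r}"
        ) from exc
    if len(lines) - 1 < n_sig:
        raise FormatError(
            f"{hea_path}: header declares {n_sig} signals but lists "
            f"{len(lines) - 1} (first missing at line {len(lines) + 1})"
        )
    signals = []
    for i, ln in enumerate(lines[1 : 1 + n_sig], start=2):
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"{hea_path}: malformed signal line {i}: {ln!r}")
        fname, fmt = parts[0], parts[1].split("x")[0].split(":")[0]
        gain, baseline, units = 200.0, 0, "mV"
        if len(parts) > 2:
            gspec = parts[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gspec, b = gspec.split("(")
                baseline = int(b.rstrip(")"))
            try:
                gain = float(gspec)
            except ValueError as exc:
                raise FormatError(
                    f"{hea_path}: bad gain on signal line {i}: {ln!r}"
                ) from exc
            if gain == 0:
                gain = 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        description = " ".join(parts[8:]) if len(parts) > 8 else f"sig{i - 2}"
        signals.append(
            dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                 units=units, adc_zero=adc_zero, description=description)
        )
    return name, fs, n_samples, signals


def read_wfdb(record: str | Path, channel=None) -> SignalTrace:
    """Read a WFDB record (``record.hea`` + signal file), format 16 only.

    ``channel`` selects one signal by its header description.  ADC counts
    are converted to physical units as (adc − baseline) / gain.
    """
    record = Path(record)
    hea = record.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header not found: {hea}")
    name, fs, n_samples, signals = _parse_header(hea)
    fmts = {s["fmt"] for s in signals}
    if fmts != {"16"}:
        raise FormatError(
            f"{hea}: unsupported WFDB format(s) {sorted(fmts)}; "
            "only format 16 is supported"
        )
    files = {s["file"] for s in signals}
    if len(files) != 1:
        raise FormatError(f"{hea}: multi-file records are not supported")
    dat = record.parent / files.pop()
    raw = np.fromfile(dat, dtype="<i2")
    n_sig = len(signals)
    if n_samples:
        raw = raw[: n_samples * n_sig]
    frames = raw.reshape(-1, n_sig)
    values = np.column_stack(
        [
            (frames[:, i].astype(float) - s["baseline"]) / s["gain"]
            for i, s in enumerate(signals)
        ]
    )
    names = tuple(s["description"] for s in signals)
    units = signals[0]["units"]
    if channel is not None:
        if channel not in names:
            raise FormatError(
                f"{record}: unknown channel {channel!r}; available: {list(names)}"
            )
        idx = names.index(channel)
        values = values[:, idx]
        names = (channel,)
        units = signals[idx]["units"]
    elif values.shape[1] == 1:
        values = values[:, 0]
    return SignalTrace(
        sample_rate=fs, values=values, channel_names=names, units=units
    )


def write_wfdb(trace: SignalTrace, record: str | Path, gain: float = 1000.0) -> None:
    """Write a format-16 WFDB record pair (for interop and round trips)."""
    record = Path(record)
    values = trace.values if trace.values.ndim == 2 else trace.values[:, None]
    n, n_sig = values.shape
    adc = np.clip(np.round(values * gain), -32768, 32767).astype("<i2")
    dat_name = record.name + ".dat"
    adc.reshape(-1).tofile(record.with_suffix(".dat"))
    lines = [f"{record.name} {n_sig} {trace.sample_rate:g} {n}"]
    for i in range(n_sig):
        desc = trace.channel_names[i]
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/{trace.units} 16 0 "
            f"{int(adc[0, i])} 0 0 {desc}"
        )
    record.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_trace(path, format: str = "auto", channel=None) -> SignalTrace:
    """Read a trace from CSV or a WFDB record (auto-detected by suffix)."""
    path = Path(path)
    if format == "auto":
        if path.suffix in (".hea", ".dat") or path.with_suffix(".hea").exists():
            format = "wfdb"
        else:
            format = "csv"
    if format == "csv":
        return _read_csv(path, channel=channel)
    if format == "wfdb":
        return read_wfdb(path.with_suffix(""), channel=channel)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a nested YAML run configuration (nam.*, uim.*, imm.* keys)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
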