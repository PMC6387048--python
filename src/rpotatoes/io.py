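"""File I/O and pipeline configuration.

EDF/EDF+ recordings are read through :mod:`mne`.  Writing is done by a
minimal EDF writer (16-bit, one-second data records, uniform sampling
rate), sufficient to persist synthetic recordings and round-trip them
through the reader.  Artifact segments and expert annotations travel as
CSV interval lists with a ``start_s,end_s[,score]`` header; fitted models
as JSON (see :meth:`RiemannianPotatoes.save`).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .detection import ArtifactSegment
from .preprocessing import Recording

__all__ = [
    "PipelineConfig",
    "FormatError",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "write_trace",
]


class FormatError(ValueError):
    """Unreadable or inconsistent input file."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline, with their defaults."""

    epoch_length_s: float = 1.0
    window_s: float = 1.0
    step_fraction: float = 0.1
    lowpass_hz: float = 30.0
    k_max: int = 10
    alpha: float = 0.05
    threshold: float = 0.95
    min_duration_s: float = 0.4
    smooth_window_s: float = 0.5
    shrinkage: float = 0.0
    seed: int = 0
    fuzzy_min_fraction: float = 0.10
    fuzzy_max_lenient_s: float = 1.5

    def __post_init__(self):
        for name in (
            "epoch_length_s",
            "window_s",
            "lowpass_hz",
            "min_duration_s",
            "smooth_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# EDF


def _edf_header_sample_counts(path) -> list[int]:
    """Samples-per-record per signal straight from the EDF header, used to
    reject mixed-rate files before delegating the actual read to mne."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated or empty EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable EDF header") from exc
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal header")
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    counts = []
    for i in range(ns):
        raw = sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()
        counts.append(int(raw))
    return counts


def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Load an EDF/EDF+ file into a Recording (microvolts).

    All signals must share one sampling rate; a channel subset may be
    selected by label.  EDF annotation channels are ignored.
    """
    import mne

    counts = _edf_header_sample_counts(path)
    if len(set(counts)) > 1:
        raise FormatError(
            f"{path}: signals have differing sampling rates {sorted(set(counts))}; "
            "resample externally before loading"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if channels is not None:
        missing = set(channels) - set(raw.ch_names)
        if missing:
            raise FormatError(f"{path}: channels not found: {sorted(missing)}")
        raw.pick(channels)
    return Recording(
        signals=raw.get_data() * 1e6,  # mne loads EEG in volts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a plain EDF file (16-bit, 1-s data records).

    Per-channel physical scaling uses the channel's own range, so the
    quantization error is bounded by range/2^16.  Trailing samples that do
    not fill a whole one-second record are dropped (with a warning).
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record")
    if rec.n_samples % spr:
        warnings.warn("dropping trailing partial second for EDF export")
    n = rec.n_channels
    data = rec.signals[:, : n_records * spr]

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field("X X X X", 80))
        fh.write(_ascii_field("Startdate X X X X", 80))
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(256 * (n + 1), 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(n_records, 8))
        fh.write(_ascii_field(1, 8))
        fh.write(_ascii_field(n, 4))
        for name in rec.channel_names:
            fh.write(_ascii_field(name, 16))
        for _ in range(n):
            fh.write(_ascii_field("", 80))  # transducer
        for _ in range(n):
            fh.write(_ascii_field("uV", 8))
        for v in phys_min:
            fh.write(_ascii_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_ascii_field(f"{v:.6g}"[:8], 8))
        fh.write(_ascii_field(dig_min, 8) * n)
        fh.write(_ascii_field(dig_max, 8) * n)
        for _ in range(n):
            fh.write(_ascii_field("", 80))  # prefiltering
        fh.write(_ascii_field(spr, 8) * n)
        fh.write(_ascii_field("", 32) * n)

        # headers round physical limits to 8 ascii chars; scale with the
        # values as written so the reader inverts exactly
        pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
        gain = (dig_max - dig_min) / (pmax - pmin)
        for r in range(n_records):
            block = data[:, r * spr : (r + 1) * spr]
            digital = np.rint((block - pmin[:, None]) * gain[:, None] + dig_min)
            digital = np.clip(digital, dig_min, dig_max).astype("<i2")
            fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path, source: str = "expert") -> list[ArtifactSegment]:
    """Read a CSV interval list (start_s, end_s[, score]).

    Intervals are validated (end > start, non-negative), sorted, and
    overlapping rows are merged with a warning.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not {"start_s", "end_s"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns start_s,end_s")
    rows = []
    for i, row in df.iterrows():
        start, end = float(row["start_s"]), float(row["end_s"])
        if not np.isfinite(start) or not np.isfinite(end) or start < 0 or end <= start:
            raise FormatError(f"{path}: invalid interval on line {i + 2}")
        score = float(row["score"]) if "score" in df.columns else float("nan")
        rows.append((start, end, score))
    rows.sort()
    merged: list[list[float]] = []
    overlapped = False
    for start, end, score in rows:
        if merged and start < merged[-1][1]:
            overlapped = True
            merged[-1][1] = max(merged[-1][1], end)
            prev = merged[-1][2]
            if not (np.isnan(prev) and np.isnan(score)):
                merged[-1][2] = np.nanmax([prev, score])
        else:
            merged.append([start, end, score])
    if overlapped:
        warnings.warn(f"{path}: overlapping intervals merged")
    return [
        ArtifactSegment(start_s=s, end_s=e, peak_score=p, source=source)
        for s, e, p in merged
    ]


def write_annotations(segments: list[ArtifactSegment], path) -> None:
    pd.DataFrame(
        {
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "score": [s.peak_score for s in segments],
        }
    ).to_csv(path, index=False)


def write_trace(trace, path) -> None:
    """Per-sample outlier-probability trace as CSV (sample, p_outlier)."""
    pd.DataFrame(
        {"sample": np.arange(trace.p_outlier.size), "p_outlier": trace.p_outlier}
    ).to_csv(path, index=False)
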