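"""Readers and writers for signals, annotations, features, models, reports.

Formats are deliberately minimal and standard: EDF/EDF+ for recorded
signals (read through :mod:`mne`), RFC-4180 CSV with a header row for
signals, annotations and feature tables, and JSON for models and
evaluation reports. Every reader raises a typed error on malformed
input — never a silent partial read.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import EvaluationReport, SpO2SVMClassifier
from .errors import FormatError, InputIOError, SchemaError
from .features import FEATURE_NAMES
from .signal import AnnotationSet, LabeledSegment, RespiratoryEvent, SpO2Signal

# ---------------------------------------------------------------------------
# SpO2 signals


def read_spo2_csv(
    path: str | os.PathLike,
    time_column: str = "time_sec",
    value_column: str = "spo2",
) -> SpO2Signal:
    """Read a two-column time/saturation CSV.

    The time column must be strictly increasing and uniformly spaced
    within 1% of the median step; the sampling rate is inferred from the
    median step. Non-numeric saturation cells become masked samples.
    """
    if not os.path.exists(path):
        raise InputIOError(f"signal file not found: {path}")
    df = pd.read_csv(path)
    for col in (time_column, value_column):
        if col not in df.columns:
            raise FormatError(f"column '{col}' not in {path} (has {list(df.columns)})")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 data rows, got {len(df)}")
    t = pd.to_numeric(df[time_column], errors="coerce").to_numpy(dtype=float)
    if np.isnan(t).any():
        row = int(np.flatnonzero(np.isnan(t))[0])
        raise FormatError(f"{path}: non-numeric timestamp at data row {row + 1}")
    steps = np.diff(t)
    if (steps <= 0).any():
        row = int(np.flatnonzero(steps <= 0)[0])
        raise FormatError(f"{path}: timestamps not increasing at data row {row + 2}")
    med = float(np.median(steps))
    off = np.abs(steps - med) > 0.01 * med
    if off.any():
        row = int(np.flatnonzero(off)[0])
        raise FormatError(
            f"{path}: non-uniform sampling at data row {row + 2} "
            f"(step {steps[row]:.6g} s vs median {med:.6g} s)"
        )
    vals = pd.to_numeric(df[value_column], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(vals)
    return SpO2Signal(
        values=np.where(valid, vals, 0.0),
        sampling_rate=1.0 / med,
        start_time=float(t[0]),
        valid=valid,
    )


def write_spo2_csv(
    signal: SpO2Signal,
    path: str | os.PathLike,
    time_column: str = "time_sec",
    value_column: str = "spo2",
) -> None:
    t = signal.start_time + np.arange(len(signal)) / signal.sampling_rate
    vals = [
        repr(float(v)) if ok else "NaN"
        for v, ok in zip(signal.values, signal.valid)
    ]
    df = pd.DataFrame({time_column: [repr(float(x)) for x in t], value_column: vals})
    df.to_csv(path, index=False, lineterminator="\n")


def read_spo2_edf(path: str | os.PathLike, channel: str = "SpO2") -> SpO2Signal:
    """Read one saturation channel from an EDF/EDF+ file.

    ``channel`` is matched case-insensitively as a substring against the
    channel labels; exactly one label must match (pass the full label to
    disambiguate).
    """
    if not os.path.exists(path):
        raise InputIOError(f"EDF file not found: {path}")
    import mne  # deferred: heavy import

    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # mne raises various types on bad files
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    matches = [ch for ch in raw.ch_names if channel.lower() in ch.lower()]
    if len(matches) != 1:
        raise FormatError(
            f"{path}: pattern '{channel}' matches {len(matches)} channels "
            f"of {raw.ch_names}; need exactly one"
        )
    raw = raw.pick(matches)
    raw.load_data(verbose="error")
    values = raw.get_data()[0]
    return SpO2Signal(values=values, sampling_rate=float(raw.info["sfreq"]))


def write_edf_fixture(
    path: str | os.PathLike,
    channels: Sequence[tuple[str, np.ndarray]],
    sampling_rate: float,
) -> None:
    """Write a minimal EDF file (testing/fixture use only).

    16-bit samples, physical range 0-100%, one-second data records. Not
    a general-purpose EDF exporter; just enough of the format for the
    reader round-trip and for generating reader test fixtures.
    """
    ns = len(channels)
    n_per_rec = int(round(sampling_rate))
    if abs(sampling_rate - n_per_rec) > 1e-9 or n_per_rec < 1:
        raise FormatError("EDF fixture writer needs an integer sampling rate")
    nsamp = len(channels[0][1])
    for _, x in channels:
        if len(x) != nsamp:
            raise FormatError("all EDF channels must share a length")
    nrec = nsamp // n_per_rec

    def pad(s: str, n: int) -> bytes:
        return s.ljust(n)[:n].encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("EDF+C", 44),
            pad(str(nrec), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    per_signal = [
        [pad(lbl, 16) for lbl, _ in channels],
        [pad("", 80)] * ns,  # transducer
        [pad("%", 8)] * ns,  # physical dimension
        [pad("0", 8)] * ns,  # physical min
        [pad("100", 8)] * ns,  # physical max
        [pad("-32768", 8)] * ns,  # digital min
        [pad("32767", 8)] * ns,  # digital max
        [pad("", 80)] * ns,  # prefiltering
        [pad(str(n_per_rec), 8)] * ns,
        [pad("", 32)] * ns,  # reserved
    ]
    scale = 65535.0 / 100.0
    with open(path, "wb") as fh:
        fh.write(hdr)
        for block in per_signal:
            fh.write(b"".join(block))
        for r in range(nrec):
            for _, x in channels:
                seg = np.asarray(x[r * n_per_rec : (r + 1) * n_per_rec], float)
                dig = np.round(np.clip(seg, 0, 100) * scale - 32768).astype("<i2")
                fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read events from a CSV with columns onset_sec, duration_sec,
    event_type; returns a validated, onset-sorted set."""
    if not os.path.exists(path):
        raise InputIOError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    needed = {"onset_sec", "duration_sec", "event_type"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation CSV needs columns {sorted(needed)}, "
            f"has {list(df.columns)}"
        )
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        onset = float(row.onset_sec)
        dur = float(row.duration_sec)
        if onset < 0:
            raise FormatError(f"{path}: negative onset at data row {i + 1}")
        if not dur > 0:
            raise FormatError(f"{path}: non-positive duration at data row {i + 1}")
        events.append(RespiratoryEvent(onset, dur, str(row.event_type)))
    return AnnotationSet(events)


def write_annotations(annotations: AnnotationSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "onset_sec": [e.onset_sec for e in annotations],
            "duration_sec": [e.duration_sec for e in annotations],
            "event_type": [e.event_type for e in annotations],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# feature tables


def write_features_csv(
    labeled: Sequence[LabeledSegment], X: np.ndarray, path: str | os.PathLike
) -> None:
    """Feature table: the ten canonical columns plus t0 and label."""
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "t0", [ls.segment.t0 for ls in labeled])
    df["label"] = [ls.label for ls in labeled]
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_features_csv(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a feature table back as (X, y, t0)."""
    if not os.path.exists(path):
        raise InputIOError(f"feature file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing or "label" not in df.columns:
        raise FormatError(f"{path}: feature CSV missing columns {missing + ['label']}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=int)
    t0 = df["t0"].to_numpy(dtype=float) if "t0" in df.columns else np.arange(len(df)) * 60.0
    return X, y, t0


# ---------------------------------------------------------------------------
# models and reports


def write_model(model: SpO2SVMClassifier, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(feature_names=FEATURE_NAMES), fh, indent=1)
        fh.write("\n")


def read_model(path: str | os.PathLike) -> SpO2SVMClassifier:
    if not os.path.exists(path):
        raise InputIOError(f"model file not found: {path}")
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: corrupt model JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: model JSON must be an object")
    return SpO2SVMClassifier.from_dict(doc)


def write_report(report: EvaluationReport, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1)
        fh.write("\n")
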