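"""Raw SpO2 trace -> labeled one-minute 1 Hz segments.

Pipeline order is fixed: :func:`mask_noise` -> :func:`downsample_to_1hz`
-> :func:`segment_signal` -> :func:`label_segments`. Saturation values
strictly below 50% are treated as sensor noise and masked (the value is
left untouched, only the validity flag drops); segments whose invalid
fraction exceeds a threshold are discarded, and surviving gaps are
filled by linear interpolation between the nearest valid neighbours.

A one-minute epoch is labeled apnea when annotated respiratory events
cover at least ``min_overlap_sec`` (default 10 s — the clinical floor
for an apnea: a cessation of breathing lasting at least ten seconds)
of the epoch, cumulatively.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ConfigError, FormatError
from .signal import (
    LABEL_APNEA,
    LABEL_NORMAL,
    NOISE_THRESHOLD,
    SEGMENT_SECONDS,
    AnnotationSet,
    LabeledSegment,
    Segment,
    SpO2Signal,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_INVALID_FRACTION = 0.2
DEFAULT_MIN_OVERLAP_SEC = 10.0


def mask_noise(signal: SpO2Signal, threshold: float = NOISE_THRESHOLD) -> SpO2Signal:
    """Mark samples strictly below ``threshold`` %SpO2 as invalid.

    Values are never altered, only the validity mask; the operation is
    idempotent.
    """
    valid = signal.valid & ~(signal.values < threshold)
    return SpO2Signal(
        values=signal.values.copy(),
        sampling_rate=signal.sampling_rate,
        start_time=signal.start_time,
        valid=valid,
    )


def downsample_to_1hz(signal: SpO2Signal) -> SpO2Signal:
    """Reduce to 1 Hz by per-second block means over *valid* samples.

    The sampling rate must be an integer multiple of 1 Hz. An output
    second is invalid when its block contains no valid sample (its value
    is carried as 0). A trailing partial block is dropped.
    """
    rate = signal.sampling_rate
    if rate < 1 or abs(rate - round(rate)) > 1e-9:
        raise ConfigError(
            f"sampling rate {rate} Hz is not an integer multiple of 1 Hz; "
            "resample the signal before preprocessing"
        )
    k = int(round(rate))
    if k == 1:
        return SpO2Signal(
            signal.values.copy(), 1.0, signal.start_time, signal.valid.copy()
        )
    n_out = len(signal) // k
    vals = signal.values[: n_out * k].reshape(n_out, k)
    mask = signal.valid[: n_out * k].reshape(n_out, k)
    counts = mask.sum(axis=1)
    sums = np.where(mask, vals, 0.0).sum(axis=1)
    out_valid = counts > 0
    out_vals = np.where(out_valid, sums / np.maximum(counts, 1), 0.0)
    return SpO2Signal(out_vals, 1.0, signal.start_time, out_valid)


def _interpolate_invalid(samples: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid samples linearly between nearest valid neighbours;
    edge gaps take the nearest valid value (np.interp clamps)."""
    idx = np.arange(samples.shape[0])
    return np.interp(idx, idx[valid], samples[valid])


def segment_signal(
    signal: SpO2Signal,
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION,
) -> list[Segment]:
    """Cut a 1 Hz signal into non-overlapping 60-sample segments.

    Windows start at the signal start; a trailing window shorter than
    60 s is dropped. Windows whose invalid fraction exceeds
    ``max_invalid_fraction`` are discarded; in surviving windows the
    invalid samples are filled by linear interpolation and the result is
    clipped into [50, 100].
    """
    if abs(signal.sampling_rate - 1.0) > 1e-9:
        raise ConfigError("segment_signal requires a 1 Hz signal")
    n = len(signal)
    if n < SEGMENT_SECONDS:
        logger.warning("signal shorter than one segment (%d s); no segments", n)
        return []
    segments: list[Segment] = []
    for i in range(n // SEGMENT_SECONDS):
        sl = slice(i * SEGMENT_SECONDS, (i + 1) * SEGMENT_SECONDS)
        vals = signal.values[sl]
        valid = signal.valid[sl]
        invalid_frac = 1.0 - valid.mean()
        if invalid_frac > max_invalid_fraction:
            continue
        if not valid.all():
            vals = _interpolate_invalid(vals, valid)
        vals = np.clip(vals, NOISE_THRESHOLD, 100.0)
        segments.append(
            Segment(
                samples=vals,
                t0=signal.start_time + i * SEGMENT_SECONDS,
                valid_fraction=float(valid.mean()),
            )
        )
    return segments


def _overlap_with_union(t0: float, t1: float, annotations: AnnotationSet) -> float:
    """Seconds of [t0, t1) covered by the union of event intervals."""
    # events are onset-sorted; merge as we sweep
    total = 0.0
    cur_start: float | None = None
    cur_end = -np.inf
    for ev in annotations:
        s, e = ev.onset_sec, ev.end_sec
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += max(0.0, min(cur_end, t1) - max(cur_start, t0))
            cur_start, cur_end = s, e
    if cur_start is not None:
        total += max(0.0, min(cur_end, t1) - max(cur_start, t0))
    return total


def label_segments(
    segments: list[Segment],
    annotations: AnnotationSet,
    min_overlap_sec: float = DEFAULT_MIN_OVERLAP_SEC,
    event_types: list[str] | None = None,
) -> list[LabeledSegment]:
    """Attach apnea / non-apnea labels by cumulative event overlap.

    A segment is apnea iff the union of (optionally type-filtered)
    annotated events covers >= ``min_overlap_sec`` seconds of its
    minute.
    """
    anns = annotations.filtered(event_types)
    out = []
    for seg in segments:
        ov = _overlap_with_union(seg.t0, seg.t0 + SEGMENT_SECONDS, anns)
        label = LABEL_APNEA if ov >= min_overlap_sec else LABEL_NORMAL
        out.append(LabeledSegment(segment=seg, label=label))
    return out


def preprocess_record(
    signal: SpO2Signal,
    annotations: AnnotationSet,
    noise_threshold: float = NOISE_THRESHOLD,
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION,
    min_overlap_sec: float = DEFAULT_MIN_OVERLAP_SEC,
    event_types: list[str] | None = None,
) -> list[LabeledSegment]:
    """Full preprocessing chain: mask -> downsample -> segment -> label."""
    masked = mask_noise(signal, threshold=noise_threshold)
    one_hz = downsample_to_1hz(masked)
    segments = segment_signal(one_hz, max_invalid_fraction=max_invalid_fraction)
    return label_segments(
        segments, annotations, min_overlap_sec=min_overlap_sec, event_types=event_types
    )
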