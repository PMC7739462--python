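"""Core data containers for overnight oximetry.

An overnight recording is a :class:`SpO2Signal` — saturation percentages
with a sampling rate and a per-sample validity mask (missing or noisy
samples are masked, never deleted, so downstream statistics can exclude
them explicitly). Expert respiratory-event labels are an
:class:`AnnotationSet`. After preprocessing, the classification unit is
the :class:`Segment`: one minute of 1 Hz samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

#: Class encoding used throughout: the margin classifier is trained with
#: +1 = normal and -1 = abnormal (apnea), while for every evaluation
#: metric APNEA is the POSITIVE class (TP counts detected apneic
#: segments). This is the single place the dual convention lives.
LABEL_NORMAL = 1
LABEL_APNEA = -1

#: Saturation values strictly below this are sensor noise/dropout.
NOISE_THRESHOLD = 50.0

#: Segment length in seconds; fixed by the method (one-minute epochs).
SEGMENT_SECONDS = 60


@dataclass
class SpO2Signal:
    """A sampled SpO2 trace.

    Parameters
    ----------
    values : ndarray of float
        Saturation in percent. Always finite; samples whose raw value
        was missing carry 0 with ``valid=False``.
    sampling_rate : float
        Samples per second, > 0.
    start_time : float
        Offset in seconds from the start of the recording.
    valid : ndarray of bool
        Parallel mask, True where the sample is usable.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 1:
            raise FormatError("SpO2 values must be one-dimensional")
        if self.values.shape != self.valid.shape:
            raise FormatError("values and valid mask differ in length")
        if not self.sampling_rate > 0:
            raise FormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise FormatError("valid samples must be finite")
        # non-finite invalid samples are carried as 0 by convention
        bad = ~np.isfinite(self.values)
        if bad.any():
            self.values = np.where(bad, 0.0, self.values)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration_sec(self) -> float:
        return len(self) / self.sampling_rate


@dataclass(frozen=True)
class RespiratoryEvent:
    """One annotated respiratory event (apnea/hypopnea)."""

    onset_sec: float
    duration_sec: float
    event_type: str = "APNEA"

    @property
    def end_sec(self) -> float:
        return self.onset_sec + self.duration_sec


@dataclass
class AnnotationSet:
    """Validated, onset-sorted list of respiratory events."""

    events: list[RespiratoryEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, ev in enumerate(self.events):
            if ev.onset_sec < 0:
                raise FormatError(f"event {i}: negative onset {ev.onset_sec}")
            if not ev.duration_sec > 0:
                raise FormatError(f"event {i}: non-positive duration {ev.duration_sec}")
        self.events = sorted(self.events, key=lambda e: e.onset_sec)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def filtered(self, event_types: list[str] | None) -> "AnnotationSet":
        """Keep only events whose type is in ``event_types`` (None = all)."""
        if event_types is None:
            return self
        keep = [e for e in self.events if e.event_type in event_types]
        return AnnotationSet(keep)


@dataclass
class Segment:
    """One 60 s window of 1 Hz samples, after noise handling.

    Invariant: exactly 60 samples, each in [50, 100].
    """

    samples: np.ndarray
    t0: float
    valid_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (SEGMENT_SECONDS,):
            raise FormatError(
                f"segment must hold exactly {SEGMENT_SECONDS} samples, "
                f"got {self.samples.shape[0]}"
            )


@dataclass
class LabeledSegment:
    """A segment with its binary ground-truth label."""

    segment: Segment
    label: int  # LABEL_APNEA or LABEL_NORMAL

    def __post_init__(self) -> None:
        if self.label not in (LABEL_APNEA, LABEL_NORMAL):
            raise FormatError(f"label must be {LABEL_APNEA} or {LABEL_NORMAL}")
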