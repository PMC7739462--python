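"""Synthetic overnight SpO2 with ground-truth apnea annotations.

The generator emulates the morphology of real oximetry during
obstructive events: a stable baseline near 97% with slow drift and
Gaussian sensor noise, punctuated by desaturation events — the
saturation ramps down over the first half of the event, holds at full
depth, then recovers exponentially once breathing resumes. Event onsets
form a Poisson process thinned to enforce non-overlap; the returned
annotation set records the exact onsets and durations, so labels are
ground truth by construction.

Every draw is determined by the config seed, which makes the whole
pipeline testable end-to-end with no recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .signal import (
    LABEL_APNEA,
    LABEL_NORMAL,
    SEGMENT_SECONDS,
    AnnotationSet,
    LabeledSegment,
    RespiratoryEvent,
    Segment,
    SpO2Signal,
)


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults describe a moderate-severity patient: ~20 obstructive
    events per hour, desaturation dips of 6-14% from a 97% baseline,
    0.5% sensor noise, event durations 15-45 s with a 10 s resaturation
    time constant.
    """

    duration_sec: float = 7200.0
    sampling_rate: float = 8.0
    baseline_mean: float = 97.0
    baseline_drift_sd: float = 0.1  # % per sqrt(minute) random walk
    noise_sd: float = 0.5  # % Gaussian sensor noise
    event_rate: float = 20.0  # events per hour
    desat_depth_range: tuple[float, float] = (6.0, 14.0)
    event_duration_range: tuple[float, float] = (15.0, 45.0)
    resat_tau: float = 10.0  # s, exponential recovery constant
    artifact_prob: float = 0.0  # per-sample sub-50 dropout probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_sec <= 0 or self.sampling_rate <= 0:
            raise ConfigError("duration and sampling rate must be positive")
        lo, hi = self.desat_depth_range
        if not (0 < lo <= hi):
            raise ConfigError("desat_depth_range must be positive and ordered")
        dlo, dhi = self.event_duration_range
        if not (0 < dlo <= dhi):
            raise ConfigError("event_duration_range must be positive and ordered")
        if self.event_rate < 0 or self.noise_sd < 0 or self.baseline_drift_sd < 0:
            raise ConfigError("rates and noise levels must be non-negative")
        if not 0 <= self.artifact_prob < 1:
            raise ConfigError("artifact_prob must be in [0, 1)")
        if self.baseline_mean - hi < 50:
            raise ConfigError(
                "baseline_mean - max depth must stay >= 50 so events are "
                "not confused with noise"
            )


_PLACEMENT_RETRIES = 200  # per event, before the config is declared infeasible


def _draw_events(cfg: SimulationConfig, rng: np.random.Generator) -> AnnotationSet:
    """Poisson-count events placed without overlap.

    The event count is Poisson(rate x duration); each event's onset and
    duration are redrawn (bounded retries) until it fits inside the
    record and keeps one resaturation time constant clear of every
    accepted event, so the count distribution is preserved while the
    realised process never overlaps.
    """
    expected = cfg.event_rate * cfg.duration_sec / 3600.0
    n = rng.poisson(expected)
    gap = cfg.resat_tau
    placed: list[tuple[float, float]] = []  # (onset, end)
    for _ in range(n):
        for _attempt in range(_PLACEMENT_RETRIES):
            dur = rng.uniform(*cfg.event_duration_range)
            onset = rng.uniform(0.0, cfg.duration_sec - dur)
            if all(onset >= e + gap or onset + dur + gap <= s for s, e in placed):
                placed.append((onset, onset + dur))
                break
        else:
            raise ConfigError(
                f"event_rate {cfg.event_rate}/h is infeasible for "
                f"non-overlapping events of {cfg.event_duration_range} s "
                f"in {cfg.duration_sec} s"
            )
    return AnnotationSet(
        [RespiratoryEvent(s, e - s, "APNEA-O") for s, e in placed]
    )


def _event_deviation(
    t: np.ndarray, onset: float, duration: float, depth: float, resat_tau: float
) -> np.ndarray:
    """Desaturation deviation (negative) at times t for one event:
    linear ramp down over the first half, hold at -depth, exponential
    recovery after the event ends."""
    dev = np.zeros_like(t)
    ramp_end = onset + 0.5 * duration
    end = onset + duration
    in_ramp = (t >= onset) & (t < ramp_end)
    dev[in_ramp] = -depth * (t[in_ramp] - onset) / (0.5 * duration)
    in_hold = (t >= ramp_end) & (t < end)
    dev[in_hold] = -depth
    after = t >= end
    dev[after] = -depth * np.exp(-(t[after] - end) / resat_tau)
    return dev


def simulate_overnight(
    config: SimulationConfig | None = None, **overrides
) -> tuple[SpO2Signal, AnnotationSet]:
    """Generate one overnight recording and its exact annotations."""
    cfg = replace(config or SimulationConfig(), **overrides) if overrides else (
        config or SimulationConfig()
    )
    rng = np.random.default_rng(cfg.seed)
    events = _draw_events(cfg, rng)

    n = int(round(cfg.duration_sec * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    # baseline random walk, sd scaled per sqrt(minute)
    step_sd = cfg.baseline_drift_sd / np.sqrt(60.0 * cfg.sampling_rate)
    baseline = cfg.baseline_mean + np.cumsum(rng.normal(0.0, step_sd, size=n))
    values = baseline + rng.normal(0.0, cfg.noise_sd, size=n)
    for ev in events:
        depth = rng.uniform(*cfg.desat_depth_range)
        values += _event_deviation(t, ev.onset_sec, ev.duration_sec, depth, cfg.resat_tau)
    values = np.clip(values, 50.0, 100.0)
    if cfg.artifact_prob > 0:
        dropouts = rng.random(n) < cfg.artifact_prob
        values = np.where(dropouts, rng.uniform(0.0, 45.0, size=n), values)
    return SpO2Signal(values, cfg.sampling_rate), events


def _segment_samples(
    cfg: SimulationConfig, rng: np.random.Generator, apnea: bool
) -> np.ndarray:
    """One minute of 1 Hz samples; apnea minutes carry a single event
    centred in the window."""
    t = np.arange(SEGMENT_SECONDS, dtype=float)
    values = cfg.baseline_mean + rng.normal(0.0, cfg.noise_sd, size=SEGMENT_SECONDS)
    if apnea:
        duration = rng.uniform(*cfg.event_duration_range)
        duration = min(duration, SEGMENT_SECONDS - 2.0)
        depth = rng.uniform(*cfg.desat_depth_range)
        onset = 0.5 * (SEGMENT_SECONDS - duration)
        values += _event_deviation(t, onset, duration, depth, cfg.resat_tau)
    return np.clip(values, 50.0, 100.0)


def simulate_labeled_dataset(
    config: SimulationConfig | None = None,
    n_apnea: int = 400,
    n_normal: int = 600,
) -> list[LabeledSegment]:
    """Generate labeled one-minute segments directly, shuffled by seed.

    Apnea-class minutes contain one centred desaturation event; normal
    minutes are event-free baseline + noise. Labels are exact.
    """
    if n_apnea <= 0 or n_normal <= 0:
        raise ConfigError("both class counts must be positive")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    labeled: list[LabeledSegment] = []
    for i in range(n_apnea + n_normal):
        apnea = i < n_apnea
        seg = Segment(
            samples=_segment_samples(cfg, rng, apnea), t0=float(i * SEGMENT_SECONDS)
        )
        labeled.append(
            LabeledSegment(segment=seg, label=LABEL_APNEA if apnea else LABEL_NORMAL)
        )
    order = rng.permutation(len(labeled))
    return [labeled[i] for i in order]
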