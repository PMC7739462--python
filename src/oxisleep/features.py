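"""The ten per-minute SpO2 statistics and feature-matrix assembly.

Each one-minute segment (60 samples at 1 Hz) is summarised by ten
statistics, in this canonical order:

========  =====================================================
s_max     maximum saturation in the minute (%)
s_min     minimum saturation (%)
s_mean    arithmetic mean (%)
s_vari    population variance (divide by n)
correc    Pearson correlation of saturation against time index
zcount    zero crossings of the deviation from the segment mean
spslope   slope of the least-squares regression line (%/s)
abslope   absolute value of spslope
bias      intercept of the regression line (%)
dmean     delta index: mean absolute difference between the
          five consecutive 12 s block means
========  =====================================================

During an apnea the saturation dips and recovers, which depresses
``s_min``, inflates ``s_vari`` and ``dmean``, and perturbs the trend
statistics — this separation is what the downstream classifier exploits.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import FormatError
from .signal import SEGMENT_SECONDS, LabeledSegment, Segment

#: Canonical column order for every feature matrix and CSV in the package.
FEATURE_NAMES = (
    "s_max",
    "s_min",
    "s_mean",
    "s_vari",
    "correc",
    "zcount",
    "spslope",
    "abslope",
    "bias",
    "dmean",
)

DELTA_BLOCK_SECONDS = 12  # 60 s = five 12 s blocks, aligned to segment start


class FeatureVector(NamedTuple):
    s_max: float
    s_min: float
    s_mean: float
    s_vari: float
    correc: float
    zcount: int
    spslope: float
    abslope: float
    bias: float
    dmean: float


def _samples(segment: Segment | np.ndarray) -> np.ndarray:
    x = segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if x.shape != (SEGMENT_SECONDS,):
        raise FormatError(f"expected {SEGMENT_SECONDS} samples, got {x.shape}")
    return x


def basic_stats(segment: Segment | np.ndarray) -> tuple[float, float, float, float]:
    """Max, min, mean and population variance of the minute."""
    x = _samples(segment)
    return float(x.max()), float(x.min()), float(x.mean()), float(x.var())


def zero_cross_count(segment: Segment | np.ndarray) -> int:
    """Sign changes of the deviation from the segment mean.

    A deviation of exactly zero inherits the previous sign, so a plateau
    sitting at the mean never double-counts a crossing; a constant
    segment has no deviations and counts 0.
    """
    x = _samples(segment)
    d = x - x.mean()
    count = 0
    last_sign = 0
    for di in d:
        s = 0 if di == 0 else (1 if di > 0 else -1)
        if s == 0:
            continue
        if last_sign != 0 and s != last_sign:
            count += 1
        last_sign = s
    return count


def regression_features(segment: Segment | np.ndarray) -> tuple[float, float, float]:
    """OLS fit s ~ slope*t + bias over t = 0..59 s; returns
    (spslope, bias, abslope)."""
    x = _samples(segment)
    t = np.arange(SEGMENT_SECONDS, dtype=float)
    # centered closed form: exact zero slope for constant segments
    tc = t - t.mean()
    slope = float(np.dot(tc, x - x.mean()) / np.dot(tc, tc))
    bias = float(x.mean() - slope * t.mean())
    return slope, bias, abs(slope)


def correlation_coefficient(segment: Segment | np.ndarray) -> float:
    """Pearson correlation between saturation and the time index; 0 by
    convention when the segment has zero variance."""
    x = _samples(segment)
    if x.var() == 0:
        return 0.0
    t = np.arange(SEGMENT_SECONDS, dtype=float)
    return float(np.corrcoef(t, x)[0, 1])


def delta_index(segment: Segment | np.ndarray) -> float:
    """Mean absolute difference between consecutive 12 s block means."""
    x = _samples(segment)
    block_means = x.reshape(-1, DELTA_BLOCK_SECONDS).mean(axis=1)
    return float(np.abs(np.diff(block_means)).mean())


def extract_features(segment: Segment | np.ndarray) -> FeatureVector:
    """All ten statistics for one segment, in canonical order."""
    s_max, s_min, s_mean, s_vari = basic_stats(segment)
    spslope, bias, abslope = regression_features(segment)
    return FeatureVector(
        s_max=s_max,
        s_min=s_min,
        s_mean=s_mean,
        s_vari=s_vari,
        correc=correlation_coefficient(segment),
        zcount=zero_cross_count(segment),
        spslope=spslope,
        abslope=abslope,
        bias=bias,
        dmean=delta_index(segment),
    )


class SegmentFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: segments -> (n, 10) feature matrix.

    Accepts a list of :class:`Segment` / :class:`LabeledSegment` or an
    (n, 60) array of raw minute samples. ``fit`` is a no-op, so the
    transformer composes with sklearn pipelines.
    """

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            if isinstance(item, LabeledSegment):
                item = item.segment
            rows.append(extract_features(item))
        if not rows:
            raise FormatError("cannot build a feature matrix from zero segments")
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)


def build_matrix(
    labeled: Sequence[LabeledSegment],
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (input order preserved) and aligned label vector."""
    if len(labeled) == 0:
        raise FormatError("cannot build a feature matrix from zero segments")
    X = SegmentFeatureExtractor().transform(labeled)
    y = np.asarray([ls.label for ls in labeled], dtype=int)
    return X, y
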