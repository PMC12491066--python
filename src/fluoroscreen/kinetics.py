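"""Aggregation-kinetics normalization and timing comparisons.

Amyloid formation followed with a reporter dye produces a sigmoidal
fluorescence trace: a lag phase, a growth phase and a plateau.  To compare
reporter dyes run at different concentrations and gains, each raw trace is
rescaled to a fraction of its total signal (min-max, exactly [0, 1]); the
half-maximal time t50 then supports calling whether a candidate dye reports
structures earlier, concurrently with, or later than the reference reporter
(classically thioflavin T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .plate_io import KineticRead, ValidationError


@dataclass
class NormalizedKinetic:
    """A kinetic read rescaled to the [0, 1] fraction-of-total-signal scale."""

    times_h: np.ndarray
    fraction: np.ndarray
    source: KineticRead


@dataclass
class TimingCall:
    """Relation of a dye's t50 to a reference reporter's t50."""

    t50_h: float
    relation_to_reference: str  # "early" | "concurrent" | "late"
    delta_used_h: float


def normalize_kinetic(read: KineticRead) -> NormalizedKinetic:
    """Min-max rescale a trace so its minimum is 0 and maximum is 1.

    A constant trace has no defined fraction-of-total scale and raises.
    """
    if len(read) < 2:
        raise ValidationError("need at least 2 timepoints to normalize")
    lo, hi = float(read.rfu.min()), float(read.rfu.max())
    if hi == lo:
        raise ValidationError(
            f"degenerate (constant) curve for ({read.dye_id}, {read.condition_id}); "
            f"normalization undefined"
        )
    return NormalizedKinetic(read.times_h.copy(), (read.rfu - lo) / (hi - lo), read)


def half_time(curve: NormalizedKinetic, *, smooth: bool = False) -> float:
    """First upward crossing of 0.5, linearly interpolated between samples.

    With ``smooth=True`` a 3-point moving median is applied before crossing
    detection, which suppresses single-sample noise spikes.
    """
    y = curve.fraction
    if smooth:
        y = median_filter(y, size=3, mode="nearest")
    t = curve.times_h
    if y[0] >= 0.5:
        return float(t[0])
    above = np.flatnonzero(y >= 0.5)
    if above.size == 0:
        raise ValidationError(
            f"curve for ({curve.source.dye_id}, {curve.source.condition_id}) "
            f"never reaches 0.5; no half-time"
        )
    i = int(above[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:  # vertical-step degenerate case
        return float(t1)
    return float(t0 + (0.5 - y0) * (t1 - t0) / (y1 - y0))


def compare_timing(dye_t50: float, reference_t50: float, delta_h: float = 2.0) -> TimingCall:
    """Classify a dye's half-time against a reference with tolerance ``delta_h``.

    "early" when dye_t50 < reference - delta_h; "late" when
    dye_t50 > reference + delta_h; otherwise "concurrent".  The tolerance is
    explicit because early/late conclusions are otherwise qualitative.
    """
    if dye_t50 < reference_t50 - delta_h:
        relation = "early"
    elif dye_t50 > reference_t50 + delta_h:
        relation = "late"
    else:
        relation = "concurrent"
    return TimingCall(dye_t50, relation, delta_h)
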