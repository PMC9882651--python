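"""Exclusion rules and low/high velocity partitioning.

Three automated rules plus one manual channel, each an independent
boolean mask so that application order cannot matter:

* confidence: only frames with tracking confidence == 3 are retained;
* speed: frames whose velocity norm exceeds 3.05 m/s are excluded
  (momentary tracking-loss spikes; 3.05 m/s is an average jogging speed);
* calibration: samples inside calibration windows are excised;
* manual: user-supplied intervals for visually identified failures.

Retained frames are classed "low" velocity if their speed is below
0.75 m/s, else "high".  Tie conventions (documented, since the written
rules use strict "above"/"below"): speed exactly 3.05 m/s is retained,
speed exactly 0.75 m/s is classed high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CalibrationWindows
from .recording import MotionRecording

SPEED_EXCLUDE_MPS = 3.05
VELOCITY_SPLIT_MPS = 0.75
CONFIDENCE_MIN = 3

REASON_CALIBRATION = "calibration"
REASON_CONFIDENCE = "confidence"
REASON_SPEED = "speed"
REASON_MANUAL = "manual"
#: Reporting precedence when a frame violates several rules at once.
REASON_ORDER = (REASON_CALIBRATION, REASON_CONFIDENCE, REASON_SPEED, REASON_MANUAL)

CLASS_LOW = "low"
CLASS_HIGH = "high"


@dataclass
class CleanMask:
    """Per-sample retention decision with reason and velocity class.

    ``reason`` is the empty string on retained samples; ``velocity_class``
    is the empty string on excluded samples.
    """

    retained: np.ndarray
    reason: np.ndarray
    velocity_class: np.ndarray

    def __post_init__(self):
        if ((self.reason != "") != ~self.retained).any():
            raise ValueError("reason must be defined exactly on excluded samples")
        if ((self.velocity_class != "") != self.retained).any():
            raise ValueError("velocity_class must be defined exactly on retained samples")

    @property
    def low(self) -> np.ndarray:
        return self.velocity_class == CLASS_LOW

    @property
    def high(self) -> np.ndarray:
        return self.velocity_class == CLASS_HIGH


def filter_confidence(rec: MotionRecording,
                      confidence_min: int = CONFIDENCE_MIN) -> np.ndarray:
    """True where tracking confidence reaches the required level (== 3)."""
    return np.asarray(rec.confidence) >= confidence_min


def filter_speed(rec: MotionRecording,
                 threshold: float = SPEED_EXCLUDE_MPS) -> np.ndarray:
    """True where the velocity norm does not exceed the spike threshold."""
    return rec.speed <= threshold


def _interval_mask(rec: MotionRecording, intervals) -> np.ndarray:
    m = np.zeros(rec.n_samples, bool)
    for t0, t1 in intervals:
        m |= rec.time_mask(float(t0), float(t1))
    return m


def excise_calibration(rec: MotionRecording,
                       windows: list[CalibrationWindows] | None = None) -> np.ndarray:
    """True outside every calibration window (union of overlapping windows).

    With ``windows=None`` the recording's own segment labels are used.
    """
    if windows is None:
        return np.asarray(rec.segment_label) == "data"
    intervals = []
    for w in windows:
        intervals.extend(iv for iv in (w.static, w.nods, w.shakes) if iv is not None)
    return ~_interval_mask(rec, intervals)


def partition_velocity(rec: MotionRecording, retained: np.ndarray,
                       cutoff: float = VELOCITY_SPLIT_MPS) -> np.ndarray:
    """Velocity class per sample: low iff speed < cutoff (retained only)."""
    cls = np.full(rec.n_samples, "", dtype="<U4")
    retained = np.asarray(retained, bool)
    low = rec.speed < cutoff
    cls[retained & low] = CLASS_LOW
    cls[retained & ~low] = CLASS_HIGH
    return cls


def build_mask(rec: MotionRecording,
               windows: list[CalibrationWindows] | None = None,
               manual_intervals=None,
               speed_threshold: float = SPEED_EXCLUDE_MPS,
               confidence_min: int = CONFIDENCE_MIN,
               velocity_split: float = VELOCITY_SPLIT_MPS) -> CleanMask:
    """Combine the independent rules into one mask (order-free conjunction)."""
    rules = {
        REASON_CALIBRATION: excise_calibration(rec, windows),
        REASON_CONFIDENCE: filter_confidence(rec, confidence_min),
        REASON_SPEED: filter_speed(rec, speed_threshold),
    }
    if manual_intervals is not None:
        rules[REASON_MANUAL] = ~_interval_mask(rec, manual_intervals)
    retained = np.logical_and.reduce(list(rules.values()))
    reason = np.full(rec.n_samples, "", dtype="<U12")
    for name in reversed(REASON_ORDER):
        if name in rules:
            reason[~rules[name]] = name
    reason[retained] = ""
    return CleanMask(retained=retained, reason=reason,
                     velocity_class=partition_velocity(rec, retained, velocity_split))


def retention_summary(mask: CleanMask, sample_rate: float) -> dict:
    """Hours retained, per-class hours/fractions, and per-reason counts."""
    n_total = len(mask.retained)
    n_ret = int(mask.retained.sum())
    n_low = int(mask.low.sum())
    n_high = int(mask.high.sum())
    to_hours = 1.0 / (3600.0 * sample_rate)
    frac_low = n_low / n_ret if n_ret else 0.0
    frac_high = n_high / n_ret if n_ret else 0.0
    reasons = {name: int((mask.reason == name).sum()) for name in REASON_ORDER}
    return {
        "n_total": n_total,
        "n_retained": n_ret,
        "hours_retained": n_ret * to_hours,
        "n_low": n_low,
        "n_high": n_high,
        "hours_low": n_low * to_hours,
        "hours_high": n_high * to_hours,
        "fraction_low": frac_low,
        "fraction_high": frac_high,
        "excluded_by_reason": reasons,
        "n_excluded": n_total - n_ret,
    }
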