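"""Sensor-to-head frame calibration from nod/shake/static segments.

The head-mounted sensor sits at an unknown, roughly constant rotation from
the anatomical head frame.  The calibration protocol recovers it in two
steps:

1. *Axis rotation* - during the nod (pitch) and shake (yaw) segments the
   angular-velocity sample cloud concentrates along the head +Y and +Z
   axes respectively.  The dominant rotation axis of each cloud (first
   principal direction, sign fixed by positive projection onto its
   nominal sensor axis) gives the pitch and yaw axes in sensor
   coordinates; the pair is orthogonalized pitch-first and completed to a
   right-handed triad.
2. *Reid pitch offset* - during the static segment the head is held with
   Reid's baseline (canthus-to-meatus line) perpendicular to gravity, so
   the time-averaged acceleration is the gravity direction.  The residual
   rotation about the (already aligned) pitch axis that brings that
   direction to head -Z completes the anatomical alignment.

Periodic re-calibrations contain only nod/shake segments; for those the
axis rotation is re-estimated while the anatomical pitch offset is
carried forward from the most recent static segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .recording import (MotionRecording, SEGMENT_NOD, SEGMENT_SHAKE,
                        SEGMENT_STATIC)
from .rotations import GRAVITY_MAG, rotation_from_quats

logger = logging.getLogger(__name__)


class DegenerateCalibrationError(RuntimeError):
    """Calibration movements do not determine the alignment."""


@dataclass
class CalibrationWindows:
    """Time intervals (seconds) of one calibration block."""

    static: tuple[float, float] | None
    nods: tuple[float, float]
    shakes: tuple[float, float]

    def validate(self, t_min: float, t_max: float) -> None:
        ivs = [iv for iv in (self.static, self.nods, self.shakes) if iv is not None]
        for t0, t1 in ivs:
            if t1 - t0 < 1.0:
                raise ValueError("calibration interval shorter than 1 s")
            if t0 < t_min - 1e-9 or t1 > t_max + 1e-9:
                raise ValueError("calibration interval outside recording bounds")
        ivs = sorted(ivs)
        for (a0, a1), (b0, b1) in zip(ivs[:-1], ivs[1:]):
            if b0 < a1 - 1e-6:
                raise ValueError("calibration intervals overlap")


@dataclass
class AlignmentResult:
    """Proper rotation carrying sensor-frame vectors into the head frame."""

    R_sensor_head: np.ndarray
    axis_residual_deg: float
    reid_pitch_offset_deg: float = float("nan")

    def __post_init__(self):
        R = np.asarray(self.R_sensor_head, float)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("R_sensor_head is not a proper rotation")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_matrix(self.R_sensor_head)


def _principal_axis(omega: np.ndarray, nominal: np.ndarray,
                    min_rms: float = 0.05) -> np.ndarray:
    """First principal direction of an angular-velocity cloud.

    The sign is chosen so the axis has positive projection on its nominal
    head axis (assumes sensor-on-head misalignment below 90 degrees).
    """
    w = np.asarray(omega, float)
    rms = float(np.sqrt(np.mean(np.sum(w ** 2, axis=1))))
    if rms < min_rms:
        raise DegenerateCalibrationError(
            f"angular velocity RMS {rms:.3f} rad/s too low for calibration")
    # principal direction of the second-moment matrix (no mean removal:
    # oscillatory movements are zero-mean by construction)
    _, vecs = np.linalg.eigh(w.T @ w)
    axis = vecs[:, -1]
    if axis @ np.asarray(nominal, float) < 0:
        axis = -axis
    return axis


def _lowpass(omega: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass denoising of a gyro series.

    The calibration movements are slow (~0.5 Hz), so a gentle cutoff
    removes most sensor noise without touching the signal; a filter
    applied per component leaves the rotation axis of a single-axis
    movement exactly unchanged.
    """
    from scipy.signal import butter, filtfilt
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return omega
    b, a = butter(4, cutoff_hz / (fs / 2))
    padlen = 3 * max(len(a), len(b))
    if len(omega) <= padlen:
        return omega
    return filtfilt(b, a, omega, axis=0)


def estimate_axis_rotation(omega_nod: np.ndarray,
                           omega_shake: np.ndarray,
                           fs: float = 62.5,
                           lowpass_hz: float = 2.5) -> AlignmentResult:
    """Rotation carrying the recovered (pitch, yaw) axes to head (+Y, +Z).

    The series are low-pass denoised (zero-phase, ``lowpass_hz``), then
    each axis is the first principal direction of its angular-velocity
    cloud.  The pitch axis is primary: the yaw axis is made orthogonal to
    it and the third axis follows by right-handed cross product.  The
    reported residual is the angle between the raw and orthogonalized yaw
    axes.
    """
    omega_nod = _lowpass(np.asarray(omega_nod, float), fs, lowpass_hz)
    omega_shake = _lowpass(np.asarray(omega_shake, float), fs, lowpass_hz)
    pitch_axis = _principal_axis(omega_nod, [0.0, 1.0, 0.0])
    yaw_raw = _principal_axis(omega_shake, [0.0, 0.0, 1.0])
    separation = np.degrees(np.arccos(np.clip(abs(pitch_axis @ yaw_raw), 0, 1)))
    if separation < 30.0:
        raise DegenerateCalibrationError(
            f"nod and shake axes only {separation:.1f} deg apart")
    yaw_axis = yaw_raw - (yaw_raw @ pitch_axis) * pitch_axis
    yaw_axis = yaw_axis / np.linalg.norm(yaw_axis)
    x_axis = np.cross(pitch_axis, yaw_axis)
    residual = np.degrees(np.arccos(np.clip(yaw_raw @ yaw_axis, -1, 1)))
    # rows are the head axes expressed in sensor coordinates
    R = np.vstack([x_axis, pitch_axis, yaw_axis])
    return AlignmentResult(R_sensor_head=R, axis_residual_deg=float(residual))


def estimate_reid_pitch_offset(a_static: np.ndarray, R_axes: np.ndarray,
                               motion_sd_threshold: float = 2.0) -> float:
    """Pitch offset (degrees) aligning measured gravity with head -Z.

    ``a_static`` is the sensed acceleration during the Reid's-baseline
    static segment; its time average is taken as the gravity direction.
    """
    a = np.asarray(a_static, float)
    if len(a) < 2:
        raise ValueError("static segment too short")
    g_mean = a.mean(axis=0)
    norm = np.linalg.norm(g_mean)
    if abs(norm - GRAVITY_MAG) > 0.2 * GRAVITY_MAG:
        raise ValueError(
            f"static acceleration norm {norm:.2f} m/s^2 is not within 20% of g")
    sd = float(np.sqrt(np.mean(np.sum((a - g_mean) ** 2, axis=1))))
    if sd > motion_sd_threshold:
        logger.warning("motion during static segment (accel sd %.2f m/s^2); "
                       "proceeding with the time average", sd)
    g_head = np.asarray(R_axes, float) @ (g_mean / norm)
    return float(np.degrees(np.arctan2(-g_head[0], -g_head[2])))


def compose_alignment(axes: AlignmentResult, reid_offset_deg: float) -> AlignmentResult:
    """Final R_sensor_head = Ry(-offset) @ R_axes."""
    corr = Rotation.from_euler("y", -reid_offset_deg, degrees=True).as_matrix()
    return AlignmentResult(R_sensor_head=corr @ axes.R_sensor_head,
                           axis_residual_deg=axes.axis_residual_deg,
                           reid_pitch_offset_deg=float(reid_offset_deg))


def calibrate(rec: MotionRecording, windows: CalibrationWindows,
              reid_offset_deg: float | None = None,
              edge_trim_s: float = 0.5) -> AlignmentResult:
    """Full alignment from one calibration block of a recording.

    If the block has no static segment, ``reid_offset_deg`` must supply
    the anatomical offset carried over from a previous static segment.
    ``edge_trim_s`` is shaved off both ends of each window so that the
    transient into/out of the calibration movement cannot contaminate the
    axis estimate.
    """
    windows.validate(rec.t[0], rec.t[-1] + 1.0 / rec.sample_rate)

    def trim(iv):
        t0, t1 = iv
        if t1 - t0 > 4.0 * edge_trim_s:
            return t0 + edge_trim_s, t1 - edge_trim_s
        return t0, t1

    nod = rec.omega_sensor[rec.time_mask(*trim(windows.nods))]
    shake = rec.omega_sensor[rec.time_mask(*trim(windows.shakes))]
    axes = estimate_axis_rotation(nod, shake)
    if windows.static is not None:
        a_static = rec.a_total_sensor[rec.time_mask(*trim(windows.static))]
        offset = estimate_reid_pitch_offset(a_static, axes.R_sensor_head)
    elif reid_offset_deg is not None:
        offset = float(reid_offset_deg)
    else:
        raise ValueError("no static segment and no carried-over Reid offset")
    return compose_alignment(axes, offset)


def apply_alignment(rec: MotionRecording, align: AlignmentResult,
                    sample_mask: np.ndarray | None = None) -> MotionRecording:
    """Rotate all sensor-frame channels into the head frame.

    Quaternions are composed so that they map world directly to the head
    frame afterwards.  With an identity alignment the recording is
    unchanged; applying an alignment and then its inverse restores the
    original recording (up to float round-off).
    """
    out = rec.copy()
    R = align.rotation
    if sample_mask is None:
        sel = slice(None)
    else:
        sel = np.asarray(sample_mask, bool)
        if not sel.any():
            return out
    out.a_total_sensor[sel] = R.apply(rec.a_total_sensor[sel])
    out.omega_sensor[sel] = R.apply(rec.omega_sensor[sel])
    c_new = R * rotation_from_quats(rec.q_world_head[sel])
    out.q_world_head[sel] = c_new.as_quat(scalar_first=True)
    return out


def windows_from_recording(rec: MotionRecording) -> list[CalibrationWindows]:
    """Group the recording's labelled calibration segments into blocks.

    Consecutive static/nod/shake intervals separated by less than 2 s are
    one block; blocks without a static segment are re-calibrations.
    """
    intervals = rec.calibration_intervals()
    blocks: list[list[tuple[str, float, float]]] = []
    for item in intervals:
        if blocks and item[1] - blocks[-1][-1][2] < 2.0:
            blocks[-1].append(item)
        else:
            blocks.append([item])
    out = []
    for block in blocks:
        by_label = {label: (t0, t1) for label, t0, t1 in block}
        if SEGMENT_NOD not in by_label or SEGMENT_SHAKE not in by_label:
            logger.warning("ignoring calibration block without nod+shake: %s", block)
            continue
        out.append(CalibrationWindows(static=by_label.get(SEGMENT_STATIC),
                                      nods=by_label[SEGMENT_NOD],
                                      shakes=by_label[SEGMENT_SHAKE]))
    return out


def apply_recalibrations(rec: MotionRecording,
                         windows: list[CalibrationWindows]
                         ) -> tuple[MotionRecording, list[AlignmentResult]]:
    """Piecewise alignment across periodic re-calibrations.

    Each inter-calibration span uses the alignment estimated from the
    calibration block at its start; the Reid pitch offset is carried
    forward from the most recent block that includes a static segment.  A
    failed block falls back to the previous span's alignment (logged).
    Returns the aligned recording and the per-span alignments.
    """
    if not windows:
        raise ValueError("no calibration windows supplied")
    windows = sorted(windows, key=lambda w: w.nods[0])
    starts = []
    for w in windows:
        ivs = [iv for iv in (w.static, w.nods, w.shakes) if iv is not None]
        starts.append(min(t0 for t0, _ in ivs))
    out = rec.copy()
    t_end = rec.t[-1] + 1.0 / rec.sample_rate
    alignments: list[AlignmentResult] = []
    last_offset: float | None = None
    last_good: AlignmentResult | None = None
    for k, w in enumerate(windows):
        try:
            align = calibrate(rec, w, reid_offset_deg=last_offset)
            last_offset = align.reid_pitch_offset_deg
            last_good = align
        except (DegenerateCalibrationError, ValueError) as exc:
            if last_good is None:
                raise
            logger.warning("calibration block %d failed (%s); "
                           "falling back to previous alignment", k, exc)
            align = last_good
        alignments.append(align)
        span_start = starts[k] if k > 0 else rec.t[0]
        span_stop = starts[k + 1] if k + 1 < len(windows) else t_end
        span = rec.time_mask(span_start, span_stop)
        aligned = apply_alignment(rec, align, sample_mask=span)
        out.a_total_sensor[span] = aligned.a_total_sensor[span]
        out.omega_sensor[span] = aligned.omega_sensor[span]
        out.q_world_head[span] = aligned.q_world_head[span]
    return out, alignments
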