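"""Rotation conventions and small kinematics helpers.

Conventions used throughout the package:

* World frame: right-handed, Z up; gravity is ``(0, 0, -9.81)`` m/s^2.
* Head frame: X nasal-occipital (+ forward), Y interaural (+ left),
  Z dorsal-ventral (+ up).
* Angles: intrinsic yaw-pitch-roll (Z-Y'-X'') decomposition of the head
  *attitude* (head -> world rotation), with positive pitch = upward
  (extension) and positive roll = left-ear-down.  Downward (forward)
  pitch is therefore negative.
* Stored quaternions are Hamilton, scalar-first unit quaternions encoding
  the passive world -> sensor (after alignment: world -> head) coordinate
  transform, i.e. ``v_sensor = R(q) @ v_world``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

#: Gravity in world coordinates, m/s^2 (world Z up).
GRAVITY_WORLD = np.array([0.0, 0.0, -9.81])
GRAVITY_MAG = 9.81


def attitude_from_angles(yaw_deg, pitch_deg, roll_deg) -> Rotation:
    """Head attitude (head -> world) from yaw/pitch/roll in degrees.

    The attitude is composed intrinsically as Rz(yaw) * Ry(-pitch) *
    Rx(-roll); the sign flips implement positive-pitch-up and positive
    roll-left-ear-down under a right-handed frame with Y pointing left.
    """
    yaw = np.asarray(yaw_deg, dtype=float)
    angles = np.stack(
        [yaw, -np.asarray(pitch_deg, float), -np.asarray(roll_deg, float)], axis=-1
    )
    return Rotation.from_euler("ZYX", angles, degrees=True)


def angles_from_attitude(attitude: Rotation):
    """Inverse of :func:`attitude_from_angles`; returns (yaw, pitch, roll) deg."""
    zyx = attitude.as_euler("ZYX", degrees=True)
    zyx = np.atleast_2d(zyx)
    yaw, pitch, roll = zyx[:, 0], -zyx[:, 1], -zyx[:, 2]
    return yaw, pitch, roll


def quats_from_world_to_frame(world_to_frame: Rotation) -> np.ndarray:
    """Scalar-first unit quaternions for a world->frame transform."""
    return world_to_frame.as_quat(scalar_first=True)


def rotation_from_quats(q: np.ndarray) -> Rotation:
    """Rotation object from stored scalar-first quaternions (world->frame)."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True)


def quat_norm_error(q: np.ndarray) -> np.ndarray:
    return np.abs(np.linalg.norm(np.asarray(q, float), axis=-1) - 1.0)


def angular_velocity_body(world_to_frame: Rotation, dt: float) -> np.ndarray:
    """Body-frame angular velocity (rad/s) from an orientation sequence.

    Uses the body-frame composition A(t+dt) = A(t) * exp([w dt]x) of the
    attitude A = world_to_frame^-1, differenced centrally (one-sided at the
    ends).  For a nod about the head +Y axis with increasing angle this
    returns +Y angular velocity.
    """
    att = world_to_frame.inv()
    n = len(att)
    if n < 2:
        raise ValueError("need at least two samples to differentiate")
    omega = np.empty((n, 3))
    rel = att[:-2].inv() * att[2:]
    omega[1:-1] = rel.as_rotvec() / (2.0 * dt)
    omega[0] = (att[0].inv() * att[1]).as_rotvec() / dt
    omega[-1] = (att[-2].inv() * att[-1]).as_rotvec() / dt
    return omega


def rotation_angle_deg(a: Rotation, b: Rotation) -> float:
    """Geodesic angle (degrees) between two rotations."""
    return float(np.degrees((a * b.inv()).magnitude()))


def rotation_about(axis: np.ndarray, angle_deg) -> Rotation:
    """Rotation(s) about a fixed unit axis by angle(s) in degrees."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ang = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return Rotation.from_rotvec(np.multiply.outer(ang, axis))
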