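"""The 6-DOF head odometry container and its delimited-text round trip.

A :class:`MotionRecording` is the pipeline's universal input: a uniform-rate
stream of timestamps, world->sensor orientation quaternions, world-frame
linear velocity, sensor-frame total linear acceleration (gravitational +
inertial), sensor-frame angular velocity, an integer tracking-confidence
channel (0 poor .. 3 good), and a per-sample segment label that tiles the
time axis (plain data vs. the static / nod / shake calibration segments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rotations import quat_norm_error

SEGMENT_DATA = "data"
SEGMENT_STATIC = "static_cal"
SEGMENT_NOD = "nod_cal"
SEGMENT_SHAKE = "shake_cal"
SEGMENT_LABELS = (SEGMENT_DATA, SEGMENT_STATIC, SEGMENT_NOD, SEGMENT_SHAKE)

_COLUMNS = [
    "t", "qw", "qx", "qy", "qz", "vx", "vy", "vz",
    "ax", "ay", "az", "wx", "wy", "wz", "confidence", "segment",
]


@dataclass
class MotionRecording:
    """Uniform-rate 6-DOF odometry stream.

    Attributes
    ----------
    t : (n,) seconds, strictly increasing, uniform at 1/sample_rate.
    q_world_head : (n, 4) scalar-first unit quaternions, passive
        world->sensor transform (world->head once aligned).
    v_world : (n, 3) linear velocity, m/s, world frame.
    a_total_sensor : (n, 3) total linear acceleration (gravitational +
        inertial), m/s^2, sensor frame.
    omega_sensor : (n, 3) angular velocity, rad/s, sensor frame.
    confidence : (n,) integer tracking confidence in {0, 1, 2, 3}.
    segment_label : (n,) one of ``data``/``static_cal``/``nod_cal``/``shake_cal``.
    truth : optional generator-internal ground truth (never serialized).
    """

    t: np.ndarray
    q_world_head: np.ndarray
    v_world: np.ndarray
    a_total_sensor: np.ndarray
    omega_sensor: np.ndarray
    confidence: np.ndarray
    segment_label: np.ndarray
    sample_rate: float
    truth: dict | None = field(default=None, repr=False, compare=False)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def speed(self) -> np.ndarray:
        """Euclidean norm of the world-frame velocity (frame-invariant)."""
        return np.linalg.norm(self.v_world, axis=1)

    def copy(self) -> "MotionRecording":
        return replace(
            self,
            t=self.t.copy(),
            q_world_head=self.q_world_head.copy(),
            v_world=self.v_world.copy(),
            a_total_sensor=self.a_total_sensor.copy(),
            omega_sensor=self.omega_sensor.copy(),
            confidence=self.confidence.copy(),
            segment_label=self.segment_label.copy(),
            truth=None if self.truth is None else dict(self.truth),
        )

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t0 <= t < t1."""
        return (self.t >= t0) & (self.t < t1)

    def validate(self, quat_tol: float = 1e-6) -> None:
        n = self.n_samples
        for name in ("q_world_head", "v_world", "a_total_sensor",
                     "omega_sensor", "confidence", "segment_label"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-6):
            raise ValueError("timestamps are not uniform at 1/sample_rate")
        if np.any(quat_norm_error(self.q_world_head) > quat_tol):
            raise ValueError("non-unit quaternion in recording")
        if not np.isin(self.confidence, [0, 1, 2, 3]).all():
            raise ValueError("confidence values outside {0,1,2,3}")
        if not np.isin(self.segment_label, SEGMENT_LABELS).all():
            raise ValueError("unknown segment label")

    # -- calibration bookkeeping -----------------------------------------
    def segment_runs(self) -> list[tuple[str, int, int]]:
        """Contiguous (label, start_index, stop_index) runs; stop exclusive."""
        labels = np.asarray(self.segment_label)
        change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [len(labels)]])
        return [(str(labels[i]), int(i), int(j)) for i, j in zip(starts, stops)]

    def calibration_intervals(self) -> list[tuple[str, float, float]]:
        """(label, t_start, t_stop) for every non-data segment."""
        out = []
        for label, i, j in self.segment_runs():
            if label != SEGMENT_DATA:
                t_stop = self.t[j - 1] + 1.0 / self.sample_rate
                out.append((label, float(self.t[i]), float(t_stop)))
        return out

    # -- delimited text IO -------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "qw": self.q_world_head[:, 0], "qx": self.q_world_head[:, 1],
            "qy": self.q_world_head[:, 2], "qz": self.q_world_head[:, 3],
            "vx": self.v_world[:, 0], "vy": self.v_world[:, 1], "vz": self.v_world[:, 2],
            "ax": self.a_total_sensor[:, 0], "ay": self.a_total_sensor[:, 1],
            "az": self.a_total_sensor[:, 2],
            "wx": self.omega_sensor[:, 0], "wy": self.omega_sensor[:, 1],
            "wz": self.omega_sensor[:, 2],
            "confidence": self.confidence,
            "segment": self.segment_label,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_rate: float | None = None,
                       renormalize_quats: bool = True) -> "MotionRecording":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        t = df["t"].to_numpy(float)
        if sample_rate is None:
            if len(t) < 2:
                raise ValueError("cannot infer sample rate from < 2 samples")
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        q = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
        if renormalize_quats:
            q = q / np.linalg.norm(q, axis=1, keepdims=True)
        return cls(
            t=t,
            q_world_head=q,
            v_world=df[["vx", "vy", "vz"]].to_numpy(float),
            a_total_sensor=df[["ax", "ay", "az"]].to_numpy(float),
            omega_sensor=df[["wx", "wy", "wz"]].to_numpy(float),
            confidence=df["confidence"].to_numpy(int),
            segment_label=df["segment"].to_numpy(str),
            sample_rate=float(sample_rate),
        )

    def write_csv(self, path, float_format: str = "%.10g",
                  sidecar: dict | None = None) -> None:
        """Write one row per sample; optional JSON sidecar next to the file.

        Header comment lines record the frame conventions so every exported
        file is self-describing.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# headstats MotionRecording\n")
            fh.write("# frames: world Z-up, gravity (0,0,-9.81) m/s^2; "
                     "head X forward, Y left, Z up; "
                     "positive pitch = up, positive roll = left-ear-down\n")
            fh.write("# quaternions: Hamilton scalar-first, passive world->sensor\n")
            self.to_dataframe().to_csv(fh, index=False, float_format=float_format)
        if sidecar is not None:
            with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
                json.dump(sidecar, fh, indent=2, default=str)

    @classmethod
    def read_csv(cls, path, sample_rate: float | None = None) -> "MotionRecording":
        df = pd.read_csv(path, comment="#")
        return cls.from_dataframe(df, sample_rate=sample_rate)
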