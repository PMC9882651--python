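"""Shared fixtures: small synthetic recordings and hand-built streams."""

from __future__ import annotations

import numpy as np
import pytest

from headstats.recording import MotionRecording
from headstats.synthetic import SimConfig, simulate_recording


def make_plain_recording(n: int = 100, fs: float = 62.5,
                         confidence: np.ndarray | None = None,
                         v_world: np.ndarray | None = None,
                         segment_label: np.ndarray | None = None) -> MotionRecording:
    """Identity-orientation recording for rule/bookkeeping tests."""
    t = np.arange(n) / fs
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    a = np.tile([0.0, 0.0, -9.81], (n, 1))
    return MotionRecording(
        t=t, q_world_head=q,
        v_world=np.zeros((n, 3)) if v_world is None else v_world,
        a_total_sensor=a,
        omega_sensor=np.zeros((n, 3)),
        confidence=np.full(n, 3) if confidence is None else confidence,
        segment_label=(np.full(n, "data", dtype="<U10")
                       if segment_label is None else segment_label),
        sample_rate=fs,
    )


@pytest.fixture(scope="session")
def rec_short() -> MotionRecording:
    """5-minute default-condition recording with a 10 deg misalignment."""
    cfg = SimConfig(seed=42, duration_s=300.0,
                    misalignment_axis=(0.2, 0.5, -0.8), misalignment_deg=10.0)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def rec_stationary() -> MotionRecording:
    """All-stationary, artifact-free, low-noise recording."""
    cfg = SimConfig(seed=7, duration_s=120.0)
    cfg.activity_transition_probs = np.array([[1.0, 0.0], [1.0, 0.0]])
    cfg.artifact_rates.confidence_drop_per_hour = 0.0
    cfg.artifact_rates.velocity_spike_per_hour = 0.0
    cfg.tracking_noise.stationary_accel_sd_mps2 = 0.02
    cfg.tracking_noise.locomotion_accel_sd_mps2 = 0.02
    cfg.tracking_noise.velocity_noise_sd_mps = 0.005
    cfg.tracking_noise.neck_lever_m = 0.0
    return simulate_recording(cfg)
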