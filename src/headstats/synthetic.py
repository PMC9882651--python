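"""Synthetic head-odometry generator.

The study's recordings (tens of hours of unconstrained natural behaviour)
are not publicly deposited, so this module generates odometry streams
with the same statistical structure the analysis assumes, making every
downstream stage testable end to end:

* an asymmetric, moderately heavy-tailed pitch distribution (downward
  bias, forward/backward one-sided variability ratio ~1.38),
* near-zero-mean, strongly leptokurtic roll,
* a two-state (stationary/locomoting) activity process at 1 Hz with
  ~92% / 8% low/high-velocity occupancy,
* a ~2 Hz locomotor line in vertical inertial acceleration,
* nod/shake/static calibration segments at the start, every ~30 minutes,
  and at the end, and
* tracking-failure artifacts (confidence drops and momentary velocity
  spikes).

Orientation dynamics are mean-reverting (Ornstein-Uhlenbeck) processes
pushed through split-normal mixture marginals (a Gaussian copula), so the
stationary marginal is exact while the temporal correlation stays a
single tunable constant.  Gravity enters the sensed acceleration as the
configured world gravity vector rotated by the stored orientation
quaternion at every sample, so the gravitational/inertial decomposition
is exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation
from scipy.special import ndtr

from .orientation import EmpiricalPrior
from .perception import NoiseModel, PsychBiasTable, _posterior_means
from .recording import (MotionRecording, SEGMENT_DATA, SEGMENT_NOD,
                        SEGMENT_SHAKE, SEGMENT_STATIC)
from .rotations import (GRAVITY_WORLD, angles_from_attitude,
                        angular_velocity_body, attitude_from_angles,
                        rotation_about, rotation_from_quats)

# ---------------------------------------------------------------------------
# marginal distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitNormal:
    """Two-piece normal: sd_below left of the mode, sd_above to the right."""

    mode: float
    sd_below: float
    sd_above: float

    def pdf(self, x):
        x = np.asarray(x, float)
        amp = math.sqrt(2.0 / math.pi) / (self.sd_below + self.sd_above)
        sd = np.where(x < self.mode, self.sd_below, self.sd_above)
        return amp * np.exp(-0.5 * ((x - self.mode) / sd) ** 2)

    def cdf(self, x):
        x = np.asarray(x, float)
        s1, s2 = self.sd_below, self.sd_above
        w = s1 + s2
        below = 2.0 * s1 / w * ndtr((x - self.mode) / s1)
        above = (s1 + s2 * (2.0 * ndtr((x - self.mode) / s2) - 1.0)) / w
        return np.where(x < self.mode, below, above)


class AngleMarginal:
    """Weighted split-normal mixture with a tabulated quantile function.

    ``support`` truncates (and renormalizes) the mixture so that sampled
    angles stay inside a physically meaningful range; pitch in particular
    must stay short of +/-90 deg where the Euler decomposition degenerates.
    """

    def __init__(self, components: list[tuple[float, SplitNormal]],
                 support: tuple[float, float] = (-89.0, 89.0)):
        total = sum(w for w, _ in components)
        self.components = [(w / total, sn) for w, sn in components]
        lo = max(min(sn.mode - 9.0 * sn.sd_below for _, sn in self.components),
                 support[0])
        hi = min(max(sn.mode + 9.0 * sn.sd_above for _, sn in self.components),
                 support[1])
        self.support = (lo, hi)
        self._grid = np.linspace(lo, hi, 20001)
        raw = self._raw_cdf(self._grid)
        self._mass = raw[-1] - raw[0]
        self._cdf = (raw - raw[0]) / self._mass

    def _raw_cdf(self, x):
        return sum(w * sn.cdf(x) for w, sn in self.components)

    def pdf(self, x):
        x = np.asarray(x, float)
        raw = sum(w * sn.pdf(x) for w, sn in self.components) / self._mass
        inside = (x >= self.support[0]) & (x <= self.support[1])
        return np.where(inside, raw, 0.0)

    def cdf(self, x):
        x = np.clip(np.asarray(x, float), *self.support)
        return (self._raw_cdf(x) - self._raw_cdf(self.support[0])) / self._mass

    def ppf(self, u):
        u = np.clip(np.asarray(u, float), 0.0, 1.0)
        return np.interp(u, self._cdf, self._grid)

    def mean(self) -> float:
        p = self.pdf(self._grid)
        return float(np.trapezoid(self._grid * p, self._grid))

    def var(self) -> float:
        p = self.pdf(self._grid)
        m = self.mean()
        return float(np.trapezoid((self._grid - m) ** 2 * p, self._grid))

    def std(self) -> float:
        return math.sqrt(self.var())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PitchMarginalConfig:
    """Split-normal-mixture pitch marginal (degrees).

    ``sd_forward`` is the scale of the downward (negative, forward) side
    below the mode; ``sd_backward`` the upward side.  A broader copy of
    the same split normal (scaled by ``tail_scale``) with weight
    ``tail_weight`` supplies the moderate excess kurtosis.
    """

    mode_deg: float = 3.6016
    sd_forward_deg: float = 16.6587
    sd_backward_deg: float = 11.2740
    tail_weight: float = 0.12
    tail_scale: float = 2.2305


@dataclass
class RollMarginalConfig:
    """Gaussian core plus heavy Gaussian tail for roll (degrees)."""

    mode_deg: float = 0.5806
    core_sd_deg: float = 4.9808
    tail_sd_deg: float = 17.3241
    tail_weight: float = 0.05


@dataclass
class LocomotionConfig:
    speed_mps: float = 1.3
    step_freq_hz: float = 2.0
    vertical_amp_mps2: float = 2.0
    #: fore-aft speed modulation at step frequency (fraction of speed)
    speed_osc_frac: float = 0.08
    #: pitch distribution during locomotion: shifted further down, slightly
    #: narrower, and more asymmetric than the stationary one
    pitch_offset_deg: float = -6.0
    pitch_scale: float = 0.9
    pitch_asymmetry_boost: float = 1.15


@dataclass
class ArtifactRates:
    confidence_drop_per_hour: float = 6.0
    velocity_spike_per_hour: float = 4.0


@dataclass
class CalibrationProtocol:
    initial_static_s: float = 15.0
    nod_count: int = 5
    shake_count: int = 5
    recal_interval_s: float = 1800.0
    movement_freq_hz: float = 0.5
    movement_amp_deg: float = 20.0

    @property
    def nod_duration_s(self) -> float:
        return self.nod_count / self.movement_freq_hz

    @property
    def shake_duration_s(self) -> float:
        return self.shake_count / self.movement_freq_hz

    @property
    def initial_block_s(self) -> float:
        return self.initial_static_s + self.nod_duration_s + self.shake_duration_s


@dataclass
class TrackingNoise:
    """Residual inertial jitter and velocity noise of the tracked stream.

    The stationary acceleration jitter stands in for the small real head
    translations (posture sway, breathing, fidgeting) that dominate the
    inertial spectrum during low-velocity epochs.
    """

    stationary_accel_sd_mps2: float = 0.78
    locomotion_accel_sd_mps2: float = 2.0
    #: deliberate stillness while holding the Reid's-baseline pose
    calibration_accel_sd_mps2: float = 0.1
    accel_corr_time_s: float = 0.08
    velocity_noise_sd_mps: float = 0.035
    velocity_corr_time_s: float = 1.0
    #: head-on-neck pivot lever arm; head rotation swings the sensor through
    #: space, which is what gives inertial acceleration its mid-frequency
    #: power along the nasal-occipital axis
    neck_lever_m: float = 0.12


def _default_transition() -> np.ndarray:
    # mean dwells ~71 s stationary / 6 s locomoting -> 92.25% stationary
    p_ls = 1.0 / 6.0
    p_sl = p_ls * (0.0775 / 0.9225)
    return np.array([[1.0 - p_sl, p_sl], [p_ls, 1.0 - p_ls]])


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording."""

    seed: int = 0
    duration_s: float = 3600.0
    sample_rate: float = 62.5
    activity_transition_probs: np.ndarray = field(default_factory=_default_transition)
    stationary_fraction_target: float = 0.9225
    pitch_marginal: PitchMarginalConfig = field(default_factory=PitchMarginalConfig)
    roll_marginal: RollMarginalConfig = field(default_factory=RollMarginalConfig)
    orientation_relaxation_time_s: float = 0.75
    #: short smoothing constant bounding sample-level angular velocity
    orientation_smoothing_time_s: float = 0.1
    locomotion: LocomotionConfig = field(default_factory=LocomotionConfig)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    calibration: CalibrationProtocol = field(default_factory=CalibrationProtocol)
    tracking_noise: TrackingNoise = field(default_factory=TrackingNoise)
    misalignment_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    misalignment_deg: float = 0.0

    def validate(self) -> None:
        P = np.asarray(self.activity_transition_probs, float)
        if P.shape != (2, 2) or np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition matrix must be 2x2 with entries in [0,1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        pm, rm = self.pitch_marginal, self.roll_marginal
        if min(pm.sd_forward_deg, pm.sd_backward_deg,
               rm.core_sd_deg, rm.tail_sd_deg) <= 0:
            raise ValueError("marginal scale parameters must be > 0")
        if not (0 <= pm.tail_weight < 1 and 0 <= rm.tail_weight < 1):
            raise ValueError("tail_weight must be in [0, 1)")
        if self.sample_rate <= 2.0 * self.locomotion.step_freq_hz:
            raise ValueError("sample_rate must exceed twice the step frequency "
                             "(Nyquist)")
        if self.duration_s < 60.0:
            raise ValueError("duration must be at least 60 s")
        if self.duration_s < self.calibration.initial_block_s:
            raise ValueError("duration shorter than the initial calibration "
                             "protocol")

    # -- derived marginals -------------------------------------------------
    def pitch_marginal_low(self) -> AngleMarginal:
        pm = self.pitch_marginal
        core = SplitNormal(pm.mode_deg, pm.sd_forward_deg, pm.sd_backward_deg)
        if pm.tail_weight == 0:
            return AngleMarginal([(1.0, core)])
        tail = SplitNormal(pm.mode_deg, pm.sd_forward_deg * pm.tail_scale,
                           pm.sd_backward_deg * pm.tail_scale)
        return AngleMarginal([(1.0 - pm.tail_weight, core), (pm.tail_weight, tail)])

    def pitch_marginal_high(self) -> AngleMarginal:
        pm, loc = self.pitch_marginal, self.locomotion
        sn = SplitNormal(
            pm.mode_deg + loc.pitch_offset_deg,
            pm.sd_forward_deg * loc.pitch_scale * loc.pitch_asymmetry_boost,
            pm.sd_backward_deg * loc.pitch_scale,
        )
        return AngleMarginal([(1.0, sn)])

    def roll_marginal_dist(self) -> AngleMarginal:
        rm = self.roll_marginal
        core = SplitNormal(rm.mode_deg, rm.core_sd_deg, rm.core_sd_deg)
        if rm.tail_weight == 0:
            return AngleMarginal([(1.0, core)], support=(-120.0, 120.0))
        tail = SplitNormal(rm.mode_deg, rm.tail_sd_deg, rm.tail_sd_deg)
        return AngleMarginal([(1.0 - rm.tail_weight, core), (rm.tail_weight, tail)],
                             support=(-120.0, 120.0))

    def pooled_pitch_density(self, x):
        """State-occupancy-weighted pitch density (the generator's target)."""
        f = self.stationary_fraction_target
        return (f * self.pitch_marginal_low().pdf(x)
                + (1.0 - f) * self.pitch_marginal_high().pdf(x))

    def expected_pitch_moments(self) -> tuple[float, float]:
        x = np.linspace(-180.0, 180.0, 36001)
        p = self.pooled_pitch_density(x)
        m = float(np.trapezoid(x * p, x))
        v = float(np.trapezoid((x - m) ** 2 * p, x))
        return m, math.sqrt(v)

    def expected_roll_moments(self) -> tuple[float, float]:
        dist = self.roll_marginal_dist()
        return dist.mean(), dist.std()


# ---------------------------------------------------------------------------
# low-level signal helpers
# ---------------------------------------------------------------------------

def _ou(n: int, dt: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck (AR(1)) series, stationary start."""
    rho = math.exp(-dt / tau)
    x0 = rng.standard_normal()
    if n == 1:
        return np.array([x0])
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - rho * rho)
    rest, _ = signal.lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
    return np.concatenate([[x0], rest])


def _smooth_ou(n: int, dt: float, tau: float, smooth: float,
               rng: np.random.Generator) -> np.ndarray:
    """OU series passed through a one-pole smoother, renormalized to unit
    variance.

    The raw AR(1) recursion is driven by white noise, so its sample-level
    derivative (hence the implied angular velocity of an orientation
    channel) diverges as dt -> 0; the smoother bounds it at ~1/smooth.
    The filtered process is still Gaussian, so pushing it through the
    copula leaves the target marginal exact.
    """
    x = _ou(n, dt, tau, rng)
    if smooth <= 0:
        return x
    r1 = math.exp(-dt / tau)
    r2 = math.exp(-dt / smooth)
    y, _ = signal.lfilter([1.0 - r2], [1.0, -r2], x, zi=np.array([r2 * x[0]]))
    var = (1.0 - r2) ** 2 * (1.0 + r1 * r2) / ((1.0 - r2 ** 2) * (1.0 - r1 * r2))
    return y / math.sqrt(var)


def _markov_states(n_sec: int, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-state chain at 1 Hz (0 stationary, 1 locomoting)."""
    denom = P[0, 1] + P[1, 0]
    pi_s = P[1, 0] / denom if denom > 0 else 1.0
    states = np.empty(n_sec, np.int8)
    states[0] = 0 if rng.random() < pi_s else 1
    u = rng.random(n_sec - 1)
    for k in range(1, n_sec):
        s = states[k - 1]
        states[k] = (1 - s) if u[k - 1] < P[s, 1 - s] else s
    return states


def _segment_schedule(config: SimConfig, n: int) -> np.ndarray:
    """Per-sample segment labels tiling the time axis."""
    fs = config.sample_rate
    cal = config.calibration
    labels = np.full(n, SEGMENT_DATA, dtype="<U10")

    def mark(t0: float, t1: float, label: str):
        i0 = max(int(round(t0 * fs)), 0)
        i1 = min(int(round(t1 * fs)), n)
        labels[i0:i1] = label

    def block(t0: float, with_static: bool):
        if with_static:
            mark(t0, t0 + cal.initial_static_s, SEGMENT_STATIC)
            t0 += cal.initial_static_s
        mark(t0, t0 + cal.nod_duration_s, SEGMENT_NOD)
        t0 += cal.nod_duration_s
        mark(t0, t0 + cal.shake_duration_s, SEGMENT_SHAKE)

    duration = n / fs
    block(0.0, with_static=True)
    recal_len = cal.nod_duration_s + cal.shake_duration_s
    final_len = cal.initial_block_s
    final_start = duration - final_len if duration >= cal.initial_block_s + final_len + 60.0 else None
    k = 1
    while final_start is not None and k * cal.recal_interval_s + recal_len < final_start - 60.0:
        block(k * cal.recal_interval_s, with_static=False)
        k += 1
    if final_start is not None:
        block(final_start, with_static=True)
    return labels


# ---------------------------------------------------------------------------
# main operations
# ---------------------------------------------------------------------------

def simulate_recording(config: SimConfig) -> MotionRecording:
    """Generate one odometry recording under the configured conditions.

    The returned recording carries a ``truth`` dict with the generator's
    internal series (inertial acceleration in the sensor frame, Euler
    angles, activity state, artifact log) for round-trip testing.
    """
    config.validate()
    fs = config.sample_rate
    dt = 1.0 / fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) * dt
    rng = np.random.default_rng([config.seed, 0x5EED])

    labels = _segment_schedule(config, n)
    cal_mask = labels != SEGMENT_DATA

    # -- activity state and speed envelope --------------------------------
    n_sec = int(np.ceil(config.duration_s))
    states_1hz = _markov_states(n_sec, np.asarray(config.activity_transition_probs, float), rng)
    state = states_1hz[np.minimum(t.astype(int), n_sec - 1)].astype(float)
    loc = config.locomotion
    target_speed = loc.speed_mps * state
    target_speed[cal_mask] = 0.0
    alpha = 1.0 - math.exp(-dt / 0.4)
    env, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], target_speed,
                            zi=np.array([(1.0 - alpha) * target_speed[0]]))
    gate = np.clip(env / loc.speed_mps, 0.0, 1.0)

    # -- orientation (Gaussian copula over OU processes) -------------------
    noise = config.tracking_noise
    heading = np.deg2rad(360.0 * rng.random() + 60.0 * _ou(n, dt, 60.0, rng))
    tau = config.orientation_relaxation_time_s
    smooth = config.orientation_smoothing_time_s
    f_low = config.pitch_marginal_low()
    f_high = config.pitch_marginal_high()
    f_roll = config.roll_marginal_dist()
    u_pitch = ndtr(_smooth_ou(n, dt, tau, smooth, rng))
    pitch = (1.0 - gate) * f_low.ppf(u_pitch) + gate * f_high.ppf(u_pitch)
    roll = f_roll.ppf(ndtr(_smooth_ou(n, dt, tau, smooth, rng)))
    yaw = np.rad2deg(heading) + 15.0 * _smooth_ou(n, dt, 5.0, smooth, rng)
    att_quat = attitude_from_angles(yaw, pitch, roll).as_quat()

    # -- calibration movements override the natural orientation -----------
    cal = config.calibration
    amp, f_mov = cal.movement_amp_deg, cal.movement_freq_hz
    run_start = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    run_stop = np.r_[run_start[1:], n]
    hold = None
    prev_label = SEGMENT_DATA
    for i0, i1 in zip(run_start, run_stop):
        label = labels[i0]
        if label == SEGMENT_DATA:
            prev_label = label
            continue
        if hold is None or prev_label == SEGMENT_DATA:
            # one hold pose per calibration block so the static -> nod ->
            # shake sequence is continuous (no spurious angular-velocity
            # spikes inside the block)
            hold = attitude_from_angles(float(yaw[i0]), 0.0, 0.0)
        prev_label = label
        m = i1 - i0
        if label == SEGMENT_STATIC:
            seg = hold * Rotation.identity(m)
        else:
            theta = amp * np.sin(2.0 * math.pi * f_mov * (t[i0:i1] - t[i0]))
            axis = "y" if label == SEGMENT_NOD else "z"
            seg = hold * Rotation.from_euler(axis, theta[:, None], degrees=True)
        att_quat[i0:i1] = seg.as_quat()
    attitude = Rotation.from_quat(att_quat)

    # -- velocity ----------------------------------------------------------
    step_phase = 2.0 * math.pi * rng.random()
    osc = 1.0 + loc.speed_osc_frac * gate * np.sin(
        2.0 * math.pi * loc.step_freq_hz * t + step_phase)
    speed_t = env * (1.0 + 0.1 * _ou(n, dt, 30.0, rng)) * osc
    speed_t = np.clip(speed_t, 0.0, None)
    vz_amp = loc.vertical_amp_mps2 / (2.0 * math.pi * loc.step_freq_hz)
    v_world = np.empty((n, 3))
    v_world[:, 0] = speed_t * np.cos(heading)
    v_world[:, 1] = speed_t * np.sin(heading)
    v_world[:, 2] = gate * vz_amp * np.sin(
        2.0 * math.pi * loc.step_freq_hz * t + step_phase + 0.5 * math.pi)
    for k in range(3):
        v_world[:, k] += noise.velocity_noise_sd_mps * _ou(
            n, dt, noise.velocity_corr_time_s, rng)
    if noise.neck_lever_m > 0:
        # head pivots about the neck: rotation swings the sensor through
        # space, giving pitch-driven nasal-occipital translation
        head_pos = attitude.apply([0.0, 0.0, noise.neck_lever_m])
        v_world += np.gradient(head_pos, dt, axis=0)

    # -- inertial acceleration --------------------------------------------
    a_inert_world = np.gradient(v_world, dt, axis=0)
    sd_t = (noise.stationary_accel_sd_mps2
            + gate * (noise.locomotion_accel_sd_mps2 - noise.stationary_accel_sd_mps2))
    sd_t[cal_mask] = noise.calibration_accel_sd_mps2
    for k in range(3):
        a_inert_world[:, k] += sd_t * _ou(n, dt, noise.accel_corr_time_s, rng)

    # -- sensor frame, misalignment, conservation --------------------------
    mis = rotation_about(np.asarray(config.misalignment_axis, float),
                         config.misalignment_deg)
    world_to_sensor = mis.inv() * attitude.inv()
    q = world_to_sensor.as_quat(scalar_first=True)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    c_s = rotation_from_quats(q)  # same path the decomposition will use
    a_inert_sensor = c_s.apply(a_inert_world)
    a_total = c_s.apply(GRAVITY_WORLD) + a_inert_sensor
    omega_sensor = angular_velocity_body(c_s, dt)
    yaw_f, pitch_f, roll_f = angles_from_attitude(attitude)

    rec = MotionRecording(
        t=t, q_world_head=q, v_world=v_world, a_total_sensor=a_total,
        omega_sensor=omega_sensor,
        confidence=np.full(n, 3, dtype=int),
        segment_label=labels, sample_rate=fs,
        truth={
            "a_inert_sensor": a_inert_sensor,
            "pitch": pitch_f, "roll": roll_f, "yaw": yaw_f,
            "state": state, "gate": gate,
            "misalignment": mis,
        },
    )
    rates = config.artifact_rates
    if rates.confidence_drop_per_hour > 0 or rates.velocity_spike_per_hour > 0:
        injection = inject_artifacts(rec, config)
        rec = injection.recording
        rec.truth["artifacts"] = injection
    return rec


@dataclass
class ArtifactInjection:
    """Recording with injected artifacts plus their bookkeeping."""

    recording: MotionRecording
    confidence_epochs: list[tuple[int, int]]
    spike_epochs: list[tuple[int, int]]

    @property
    def spike_indices(self) -> np.ndarray:
        if not self.spike_epochs:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(i0, i1) for i0, i1 in self.spike_epochs])

    @property
    def confidence_indices(self) -> np.ndarray:
        if not self.confidence_epochs:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(i0, i1) for i0, i1 in self.confidence_epochs])


def inject_artifacts(rec: MotionRecording, config: SimConfig,
                     rng: np.random.Generator | None = None) -> ArtifactInjection:
    """Insert confidence drops and momentary velocity spikes.

    Epoch times are Poisson at the configured hourly rates; spikes last
    1-5 samples with magnitude in (3.05, 8] m/s so every spike violates
    the 3.05 m/s exclusion threshold; confidence drops last 0.2-2 s with
    confidence in {0, 1, 2}.  Artifacts land only in plain data segments
    so that filter accounting stays exact.  With both rates zero the
    recording is returned unchanged.
    """
    rates = config.artifact_rates
    if rates.confidence_drop_per_hour < 0 or rates.velocity_spike_per_hour < 0:
        raise ValueError("artifact rates must be >= 0")
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xA7])
    out = rec.copy()
    out.truth = rec.truth
    hours = rec.duration / 3600.0
    fs = rec.sample_rate
    data_runs = [(i, j) for label, i, j in rec.segment_runs() if label == SEGMENT_DATA]
    lengths = np.array([j - i for i, j in data_runs], float)

    def place(epoch_len: int) -> tuple[int, int] | None:
        ok = lengths >= epoch_len
        if not ok.any():
            return None
        weights = np.where(ok, lengths, 0.0)
        run = rng.choice(len(data_runs), p=weights / weights.sum())
        i, j = data_runs[run]
        start = int(rng.integers(i, j - epoch_len + 1))
        return start, start + epoch_len

    conf_epochs: list[tuple[int, int]] = []
    n_conf = rng.poisson(rates.confidence_drop_per_hour * hours)
    for _ in range(n_conf):
        length = int(rng.integers(int(0.2 * fs), int(2.0 * fs) + 1))
        span = place(length)
        if span is None:
            continue
        out.confidence[span[0]:span[1]] = int(rng.integers(0, 3))
        conf_epochs.append(span)

    spike_epochs: list[tuple[int, int]] = []
    n_spike = rng.poisson(rates.velocity_spike_per_hour * hours)
    for _ in range(n_spike):
        length = int(rng.integers(1, 6))
        span = place(length)
        if span is None:
            continue
        magnitude = 8.0 - rng.random() * (8.0 - 3.05)  # in (3.05, 8]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        out.v_world[span[0]:span[1]] = magnitude * direction
        spike_epochs.append(span)

    return ArtifactInjection(recording=out, confidence_epochs=conf_epochs,
                             spike_epochs=spike_epochs)


# ---------------------------------------------------------------------------
# psychophysics and calibration helpers
# ---------------------------------------------------------------------------

def simulate_psych_bias(prior: EmpiricalPrior, noise: NoiseModel, angles,
                        obs_noise_sd: float, seed: int) -> PsychBiasTable:
    """Model-predicted bias at the given angles plus i.i.d. Gaussian noise."""
    angles = np.asarray(angles, float)
    if np.any(angles < prior.grid[0]) or np.any(angles > prior.grid[-1]):
        raise ValueError("angle outside the prior grid")
    predicted = _posterior_means(angles, prior, noise) - angles
    if obs_noise_sd > 0:
        rng = np.random.default_rng(seed)
        predicted = predicted + rng.normal(0.0, obs_noise_sd, size=len(angles))
    return PsychBiasTable(angles=angles, observed_bias=predicted,
                          source="synthetic")


def make_calibration_gyro(misalignment: Rotation | None = None,
                          noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None,
                          fs: float = 62.5, freq_hz: float = 0.5,
                          cycles: int = 5, amp_deg: float = 20.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Sensor-frame angular velocity for one nod + shake calibration pair.

    ``misalignment`` is the true sensor->head rotation; the returned
    series are what a gyro fixed to the sensor would record, optionally
    with additive Gaussian noise (rad/s).
    """
    if misalignment is None:
        misalignment = Rotation.identity()
    n = int(round(cycles / freq_hz * fs))
    tt = np.arange(n) / fs
    rate = np.deg2rad(amp_deg) * 2.0 * math.pi * freq_hz * np.cos(
        2.0 * math.pi * freq_hz * tt)
    omega_nod = np.outer(rate, [0.0, 1.0, 0.0])
    omega_shake = np.outer(rate, [0.0, 0.0, 1.0])
    omega_nod = misalignment.inv().apply(omega_nod)
    omega_shake = misalignment.inv().apply(omega_shake)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        omega_nod = omega_nod + rng.normal(0.0, noise_sd, omega_nod.shape)
        omega_shake = omega_shake + rng.normal(0.0, noise_sd, omega_shake.shape)
    return omega_nod, omega_shake


def analytic_pitch_prior(config: SimConfig, lo: float = -90.0, hi: float = 90.0,
                         step: float = 1.0) -> EmpiricalPrior:
    """Noise-free empirical pitch prior implied by the configuration."""
    grid = np.arange(lo, hi + step / 2, step)
    return EmpiricalPrior.from_density(grid, config.pooled_pitch_density(grid))


def analytic_roll_prior(config: SimConfig, lo: float = -120.0, hi: float = 120.0,
                        step: float = 1.0) -> EmpiricalPrior:
    grid = np.arange(lo, hi + step / 2, step)
    return EmpiricalPrior.from_density(grid, config.roll_marginal_dist().pdf(grid))
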