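"""Generator contracts: determinism, conservation, marginal and spectral
targeting, artifact bookkeeping."""

import numpy as np
import pytest

import headstats as hs
from headstats.orientation import EmpiricalPrior
from headstats.perception import NoiseModel, predict_bias_curve
from headstats.recording import SEGMENT_DATA
from headstats.spectra import power_spectrum
from headstats.synthetic import (SimConfig, inject_artifacts,
                                 simulate_psych_bias, simulate_recording)


def test_fixed_seed_is_bit_identical_and_seeds_differ():
    a = simulate_recording(SimConfig(seed=5, duration_s=120))
    b = simulate_recording(SimConfig(seed=5, duration_s=120))
    c = simulate_recording(SimConfig(seed=6, duration_s=120))
    for chan in ("q_world_head", "v_world", "a_total_sensor", "omega_sensor"):
        assert np.array_equal(getattr(a, chan), getattr(b, chan))
        assert not np.array_equal(getattr(a, chan), getattr(c, chan))


def test_recording_is_valid_and_segments_tile(rec_short):
    rec_short.validate()
    # labels tile the axis by construction; every sample has one
    assert len(rec_short.segment_label) == rec_short.n_samples
    runs = rec_short.segment_runs()
    assert runs[0][1] == 0 and runs[-1][2] == rec_short.n_samples
    for (_, _, stop), (_, start, _) in zip(runs[:-1], runs[1:]):
        assert stop == start


def test_gravity_conservation_is_exact(rec_short):
    """a_total - R(q) g_world equals the generator's inertial series."""
    dec = hs.decompose_acceleration(rec_short)
    resid = dec.a_inert - rec_short.truth["a_inert_sensor"]
    assert np.abs(resid).max() < 1e-12


def test_stationary_limit(rec_stationary):
    """All-stationary, quiet config: negligible speed, accel ~ gravity."""
    data = rec_stationary.segment_label == SEGMENT_DATA
    assert rec_stationary.speed[data].max() < 0.1
    dec = hs.decompose_acceleration(rec_stationary)
    rms = np.sqrt(np.mean(np.sum(dec.a_inert[data] ** 2, axis=1)))
    assert rms < 0.1


def test_marginal_targeting_within_three_effective_se():
    """Sampled pitch/roll moments hit the configured targets.

    Standard errors account for the temporal correlation: with relaxation
    time tau the effective sample count is ~ duration / (2 tau).
    """
    cfg = SimConfig(seed=21, duration_s=3200.0,
                    orientation_relaxation_time_s=0.2,
                    orientation_smoothing_time_s=0.05)
    cfg.artifact_rates.confidence_drop_per_hour = 0.0
    cfg.artifact_rates.velocity_spike_per_hour = 0.0
    rec = simulate_recording(cfg)
    assert rec.n_samples >= 2e5
    data = rec.segment_label == SEGMENT_DATA
    pitch = rec.truth["pitch"][data]
    roll = rec.truth["roll"][data]
    n_eff = cfg.duration_s / (2 * (cfg.orientation_relaxation_time_s
                                   + cfg.orientation_smoothing_time_s))
    exp_mean, exp_sd = cfg.expected_pitch_moments()
    se_mean = exp_sd / np.sqrt(n_eff)
    # kurtosis ~1.7 inflates the SD sampling error over the Gaussian case
    se_sd = exp_sd * np.sqrt((1.7 + 2.0) / (2.0 * n_eff))
    assert abs(pitch.mean() - exp_mean) < 3 * se_mean
    assert abs(pitch.std(ddof=1) - exp_sd) < 3 * se_sd
    r_mean, r_sd = cfg.expected_roll_moments()
    se_r_sd = r_sd * np.sqrt((7.3 + 2.0) / (2.0 * n_eff))
    assert abs(roll.mean() - r_mean) < 3 * r_sd / np.sqrt(n_eff)
    assert abs(roll.std(ddof=1) - r_sd) < 3 * se_r_sd


def test_locomotor_spectral_peak_at_step_frequency():
    """Vertical inertial acceleration peaks within one bin of 2 Hz while
    locomoting."""
    cfg = SimConfig(seed=33, duration_s=600.0)
    cfg.activity_transition_probs = np.array([[0.0, 1.0], [0.0, 1.0]])
    cfg.artifact_rates.confidence_drop_per_hour = 0.0
    cfg.artifact_rates.velocity_spike_per_hour = 0.0
    rec = simulate_recording(cfg)
    data = rec.segment_label == SEGMENT_DATA
    az = rec.truth["a_inert_sensor"][:, 2]
    freqs, psd, _, _ = power_spectrum(az, fs=62.5, nfft=512, mask=data)
    peak = freqs[1:][np.argmax(psd[1:])]
    assert abs(peak - cfg.locomotion.step_freq_hz) <= 62.5 / 512


def test_invalid_configs_raise():
    with pytest.raises(ValueError, match="duration"):
        simulate_recording(SimConfig(seed=0, duration_s=30))
    cfg = SimConfig(seed=0, duration_s=120, sample_rate=3.5)
    with pytest.raises(ValueError, match="Nyquist"):
        simulate_recording(cfg)
    cfg = SimConfig(seed=0, duration_s=120)
    cfg.activity_transition_probs = np.array([[0.7, 0.4], [0.1, 0.9]])
    with pytest.raises(ValueError, match="sum to 1"):
        simulate_recording(cfg)


class TestInjectArtifacts:
    def _clean_rec(self, seed=9, duration=600.0):
        cfg = SimConfig(seed=seed, duration_s=duration)
        cfg.artifact_rates.confidence_drop_per_hour = 0.0
        cfg.artifact_rates.velocity_spike_per_hour = 0.0
        return simulate_recording(cfg), cfg

    def test_zero_rates_leave_recording_unchanged(self):
        rec, cfg = self._clean_rec()
        res = inject_artifacts(rec, cfg)
        assert np.array_equal(res.recording.v_world, rec.v_world)
        assert np.array_equal(res.recording.confidence, rec.confidence)
        assert res.spike_epochs == [] and res.confidence_epochs == []

    def test_injected_artifacts_are_bookkept_and_over_threshold(self):
        rec, cfg = self._clean_rec()
        cfg.artifact_rates.confidence_drop_per_hour = 40.0
        cfg.artifact_rates.velocity_spike_per_hour = 40.0
        res = inject_artifacts(rec, cfg)
        assert len(res.spike_epochs) > 0 and len(res.confidence_epochs) > 0
        speeds = res.recording.speed[res.spike_indices]
        assert np.all(speeds > 3.05) and np.all(speeds <= 8.0)
        assert np.all(res.recording.confidence[res.confidence_indices] < 3)
        # spikes last 1-5 samples and land in plain data segments
        for i0, i1 in res.spike_epochs:
            assert 1 <= i1 - i0 <= 5
            assert np.all(res.recording.segment_label[i0:i1] == SEGMENT_DATA)
        # untouched samples identical to the clean recording
        touched = np.zeros(rec.n_samples, bool)
        touched[res.spike_indices] = True
        assert np.array_equal(res.recording.v_world[~touched],
                              rec.v_world[~touched])


class TestSimulatePsychBias:
    def _prior_and_noise(self):
        prior = hs.analytic_pitch_prior(SimConfig())
        return prior, NoiseModel(kind="shear", sigma=0.1)

    def test_noise_free_equals_model_prediction(self):
        prior, noise = self._prior_and_noise()
        angles = np.arange(-60.0, 61.0, 15.0)
        table = simulate_psych_bias(prior, noise, angles, 0.0, seed=1)
        curve = predict_bias_curve(prior, noise)
        assert np.allclose(table.observed_bias, curve.at(angles), atol=1e-12)

    def test_uniform_prior_gives_zero_bias(self):
        prior = EmpiricalPrior.uniform(-90, 90)
        noise = NoiseModel(kind="linear", sigma=0.02, additive_sd=2.0)
        table = simulate_psych_bias(prior, noise, [-45.0, 0.0, 45.0], 0.0, seed=1)
        assert np.abs(table.observed_bias).max() < 1e-9

    def test_angle_outside_grid_raises(self):
        prior, noise = self._prior_and_noise()
        with pytest.raises(ValueError, match="outside"):
            simulate_psych_bias(prior, noise, [120.0], 0.0, seed=1)


def test_csv_round_trip(tmp_path, rec_stationary):
    path = tmp_path / "rec.csv"
    rec_stationary.write_csv(path, sidecar={"note": "fixture"})
    back = hs.MotionRecording.read_csv(path)
    assert back.n_samples == rec_stationary.n_samples
    assert np.allclose(back.q_world_head, rec_stationary.q_world_head, atol=1e-9)
    assert np.allclose(back.v_world, rec_stationary.v_world, atol=1e-8)
    assert list(back.segment_label) == list(rec_stationary.segment_label)
    assert (path.parent / "rec.csv.json").exists()
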