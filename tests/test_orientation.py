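"""Angle extraction, moments, asymmetry, and KDE priors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from headstats.orientation import (EmpiricalPrior, asymmetry_ratio,
                                   compute_moments, estimate_kde,
                                   quaternion_to_angles, scott_bandwidth)
from headstats.rotations import attitude_from_angles
from headstats.synthetic import AngleMarginal, SplitNormal


def _quat(yaw, pitch, roll):
    return attitude_from_angles(yaw, pitch, roll).inv().as_quat(scalar_first=True)


class TestQuaternionToAngles:
    def test_identity(self):
        out = quaternion_to_angles(np.array([[1.0, 0, 0, 0]]))
        assert np.allclose([out.yaw, out.pitch, out.roll], 0.0, atol=1e-12)

    def test_single_axis_pitch(self):
        out = quaternion_to_angles(_quat(0.0, 30.0, 0.0))
        assert out.pitch[0] == pytest.approx(30.0, abs=1e-9)
        assert abs(out.roll[0]) < 1e-9 and abs(out.yaw[0]) < 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(yaw=st.floats(-179, 179), pitch=st.floats(-85, 85),
           roll=st.floats(-179, 179))
    def test_round_trip(self, yaw, pitch, roll):
        out = quaternion_to_angles(_quat(yaw, pitch, roll))
        q2 = _quat(out.yaw[0], out.pitch[0], out.roll[0])
        assert np.allclose(_quat(yaw, pitch, roll), q2, atol=1e-9) or \
            np.allclose(_quat(yaw, pitch, roll), -q2, atol=1e-9)

    def test_gimbal_flagging(self):
        out = quaternion_to_angles(_quat(0.0, 89.95, 0.0))
        assert out.gimbal_flag[0]

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError, match="non-unit"):
            quaternion_to_angles(np.array([[1.2, 0, 0, 0]]))


class TestMoments:
    def test_printed_sample_matches_definitional_sums(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
        # independent brute-force evaluation of the definitional sums
        n = len(x)
        mean = sum(x) / n
        sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
        m2 = sum((v - mean) ** 2 for v in x) / n
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        res = compute_moments(x)
        assert res.mean == pytest.approx(mean)
        assert res.sd == pytest.approx(sd)
        assert res.skewness == pytest.approx(m3 / m2 ** 1.5)
        assert res.excess_kurtosis == pytest.approx(m4 / m2 ** 2 - 3.0)

    def test_gaussian_limit(self):
        x = np.random.default_rng(11).standard_normal(100_000)
        res = compute_moments(x)
        assert abs(res.skewness) < 0.05 and abs(res.excess_kurtosis) < 0.05

    def test_laplace_excess_kurtosis(self):
        x = np.random.default_rng(12).laplace(size=200_000)
        assert compute_moments(x).excess_kurtosis == pytest.approx(3.0, abs=0.25)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.gamma(2.0, size=5000)
        a, b = compute_moments(x), compute_moments(3.0 * x + 7.0)
        assert b.mean == pytest.approx(3 * a.mean + 7)
        assert b.sd == pytest.approx(3 * a.sd)
        assert b.skewness == pytest.approx(a.skewness)
        assert b.excess_kurtosis == pytest.approx(a.excess_kurtosis)
        shuffled = compute_moments(rng.permutation(x))
        assert shuffled.skewness == pytest.approx(a.skewness)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            compute_moments([1.0, 2.0, 3.0])


class TestAsymmetry:
    def test_symmetric_gaussian_is_balanced(self):
        x = np.random.default_rng(21).standard_normal(100_000)
        res = asymmetry_ratio(x)
        assert 0.97 <= res.ratio <= 1.03

    @staticmethod
    def _density_oracle(dist, bandwidth):
        """Expected one-sided RMS ratio from the analytic density: smooth
        the density at the estimator's mode bandwidth, take the argmax as
        the mode, then integrate the raw density on each side."""
        from scipy.ndimage import gaussian_filter1d
        g = np.linspace(-120, 120, 24001)
        dx = g[1] - g[0]
        dens = dist.pdf(g)
        mode = g[np.argmax(gaussian_filter1d(dens, bandwidth / dx))]
        below, above = g < mode, g > mode
        rms = lambda side: np.sqrt(np.trapezoid((g[side] - mode) ** 2 * dens[side],
                                                g[side])
                                   / np.trapezoid(dens[side], g[side]))
        return rms(below) / rms(above)

    def test_split_normal_ratio_recovered(self):
        dist = AngleMarginal([(1.0, SplitNormal(0.0, 15.0, 10.0))])
        x = dist.ppf(np.random.default_rng(22).random(100_000))
        from headstats.orientation import scott_bandwidth
        res = asymmetry_ratio(x)
        assert res.heavier_side == "below"
        oracle = self._density_oracle(dist, 3.0 * scott_bandwidth(x))
        assert res.ratio == pytest.approx(oracle, abs=0.04)
        # with a narrow mode bandwidth the raw sd ratio is recovered
        res_narrow = asymmetry_ratio(x, bandwidth=0.5)
        assert res_narrow.ratio == pytest.approx(1.5, abs=0.06)

    def test_empty_side_raises(self):
        # a point mass at the sample floor puts the KDE mode exactly at the
        # minimum, leaving nothing strictly below it
        x = np.concatenate([np.zeros(150), [3.0]])
        with pytest.raises(ValueError, match="side"):
            asymmetry_ratio(x, bandwidth=0.5)


class TestKDE:
    def test_matches_brute_force_kernel_sum(self):
        x = np.array([-3.0, -1.0, -0.5, 0.0, 0.2, 0.9, 1.4, 2.2, 3.3, 4.0])
        prior = estimate_kde(np.tile(x, 10), (-10.0, 10.0))
        h = prior.bandwidth
        xs = np.tile(x, 10)
        oracle = np.array([
            sum(np.exp(-0.5 * ((g - xi) / h) ** 2) for xi in xs)
            / (len(xs) * h * np.sqrt(2 * np.pi))
            for g in prior.grid])
        oracle = oracle / (oracle.sum() * prior.step)
        assert np.abs(prior.density - oracle).max() < 1e-10

    def test_normalization_and_mode(self):
        x = np.random.default_rng(31).standard_normal(5000)
        prior = estimate_kde(x, (-10.0, 10.0))
        assert prior.density.sum() * prior.step == pytest.approx(1.0, abs=1e-6)
        assert abs(prior.grid[np.argmax(prior.density)]) <= 1.0
        assert (prior.density >= 0).all()

    def test_agrees_with_scipy_gaussian_kde(self):
        from scipy.stats import gaussian_kde
        x = np.random.default_rng(32).standard_normal(2000)
        prior = estimate_kde(x, (-8.0, 8.0))
        ref = gaussian_kde(x, bw_method="scott")(prior.grid)
        ref = ref / (ref.sum() * prior.step)
        # same kernel and rule up to the n^-1/5 factor's sd estimator detail
        assert np.abs(prior.density - ref).max() < 5e-3

    def test_bandwidth_continuity(self):
        x = np.random.default_rng(33).standard_normal(2000)
        h = scott_bandwidth(x)
        a = estimate_kde(x, (-8.0, 8.0), bandwidth=h)
        b = estimate_kde(x, (-8.0, 8.0), bandwidth=h * 1.01)
        assert np.abs(a.density - b.density).max() < 5e-3

    def test_out_of_range_samples_are_clipped_and_counted(self):
        x = np.concatenate([np.random.default_rng(34).standard_normal(1000),
                            [50.0, -50.0]])
        prior = estimate_kde(x, (-10.0, 10.0))
        assert prior.n_clipped == 2

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="identical"):
            estimate_kde(np.zeros(500), (-5.0, 5.0))
        with pytest.raises(ValueError, match="at least"):
            estimate_kde(np.arange(10.0), (-5.0, 5.0))


def test_prior_csv_round_trip(tmp_path):
    x = np.random.default_rng(35).standard_normal(1000)
    prior = estimate_kde(x, (-8.0, 8.0))
    path = tmp_path / "prior.csv"
    prior.to_csv(path)
    back = EmpiricalPrior.read_csv(path)
    assert np.allclose(back.density, prior.density, atol=1e-9)
    assert np.array_equal(back.grid, prior.grid)
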