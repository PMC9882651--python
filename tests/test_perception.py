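"""Bayesian tilt-perception model: noise laws, posterior bias, RSE fitting."""

import numpy as np
import pytest

from headstats.orientation import EmpiricalPrior
from headstats.perception import (NoiseModel, PsychBiasTable, fit_sigma,
                                  likelihood_sd, posterior_bias,
                                  predict_bias_curve, rse)
from headstats.synthetic import SimConfig, analytic_pitch_prior, simulate_psych_bias


def gaussian_prior(sd=20.0, lo=-90.0, hi=90.0):
    grid = np.arange(lo, hi + 0.5, 1.0)
    dens = np.exp(-0.5 * (grid / sd) ** 2)
    return EmpiricalPrior.from_density(grid, dens)


class TestLikelihoodSd:
    def test_floor_at_zero_eccentricity(self):
        for kind in ("linear", "shear"):
            noise = NoiseModel(kind=kind, sigma=0.3, additive_sd=2.0)
            assert likelihood_sd(0.0, noise) == pytest.approx(2.0)

    def test_linear_formula(self):
        noise = NoiseModel(kind="linear", sigma=0.1, additive_sd=2.0)
        assert likelihood_sd(30.0, noise) == pytest.approx(5.0)

    def test_shear_even_and_monotone_to_ninety(self):
        noise = NoiseModel(kind="shear", sigma=0.2, additive_sd=2.0)
        th = np.arange(0.0, 91.0)
        sd = likelihood_sd(th, noise)
        assert np.all(np.diff(sd) >= -1e-12)
        assert likelihood_sd(-90.0, noise) == pytest.approx(likelihood_sd(90.0, noise))

    def test_kinds_agree_at_ninety_with_default_scale(self):
        lin = NoiseModel(kind="linear", sigma=0.1)
        she = NoiseModel(kind="shear", sigma=0.1)
        assert likelihood_sd(90.0, lin) == pytest.approx(likelihood_sd(90.0, she))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            NoiseModel(kind="cubic", sigma=0.1)
        with pytest.raises(ValueError):
            NoiseModel(kind="linear", sigma=-0.1)


class TestPosteriorBias:
    def test_flat_prior_gives_zero_bias_everywhere(self):
        # angles kept far enough from the grid edge that likelihood
        # truncation is below the 1e-9 tolerance
        prior = EmpiricalPrior.uniform(-90, 90)
        noise = NoiseModel(kind="linear", sigma=0.0, additive_sd=2.0)
        curve = predict_bias_curve(prior, noise, (-60, 60))
        assert np.abs(curve.bias).max() < 1e-9

    def test_conjugate_gaussian_closed_form(self):
        sp, sl = 20.0, 5.0
        prior = gaussian_prior(sd=sp)
        noise = NoiseModel(kind="linear", sigma=0.0, additive_sd=sl)
        for theta in (-40.0, -10.0, 5.0, 30.0):
            expected = -theta * sl ** 2 / (sp ** 2 + sl ** 2)
            assert posterior_bias(theta, prior, noise) == pytest.approx(
                expected, abs=0.1)

    def test_matches_fine_grid_numerical_oracle(self):
        cfg = SimConfig()
        prior = analytic_pitch_prior(cfg)
        noise = NoiseModel(kind="linear", sigma=0.05, additive_sd=2.3)
        for theta in (-60.0, -15.0, 45.0):
            # independent oracle: direct numerical integration on a 10x
            # finer grid with the analytic (not gridded) prior density
            fine = np.arange(-90.0, 90.0001, 0.1)
            dens = cfg.pooled_pitch_density(fine)
            sd = likelihood_sd(theta, noise)
            post = dens * np.exp(-0.5 * ((fine - theta) / sd) ** 2)
            oracle = np.sum(fine * post) / np.sum(post) - theta
            assert posterior_bias(theta, prior, noise) == pytest.approx(
                oracle, abs=0.05)

    def test_symmetric_prior_gives_odd_curve(self):
        prior = gaussian_prior()
        noise = NoiseModel(kind="shear", sigma=0.1, additive_sd=2.3)
        curve = predict_bias_curve(prior, noise)
        flipped = -curve.bias[::-1]
        assert np.abs(curve.bias - flipped).max() < 1e-6

    def test_attraction_toward_symmetric_prior_mode(self):
        prior = gaussian_prior()
        noise = NoiseModel(kind="linear", sigma=0.05, additive_sd=2.3)
        curve = predict_bias_curve(prior, noise, (-80, 80))
        nz = curve.angles != 0
        assert np.all(np.sign(curve.bias[nz]) == -np.sign(curve.angles[nz]))

    def test_bias_magnitude_grows_with_likelihood_sd(self):
        prior = gaussian_prior()
        theta = 30.0
        last = 0.0
        for sl in (1.0, 3.0, 8.0, 15.0):
            noise = NoiseModel(kind="linear", sigma=0.0, additive_sd=sl)
            b = abs(posterior_bias(theta, prior, noise))
            assert b >= last - 1e-12
            last = b

    def test_prior_dominant_limit(self):
        prior = analytic_pitch_prior(SimConfig())
        noise = NoiseModel(kind="linear", sigma=0.0, additive_sd=500.0)
        theta = 40.0
        bias = posterior_bias(theta, prior, noise)
        # posterior ~ prior, so the estimate collapses to the prior mean
        assert bias == pytest.approx(prior.mean() - theta, abs=1.5)

    def test_angle_outside_grid_raises(self):
        prior = gaussian_prior()
        noise = NoiseModel(kind="linear", sigma=0.1)
        with pytest.raises(ValueError, match="outside"):
            posterior_bias(150.0, prior, noise)

    def test_posterior_normalization_before_mean(self):
        # the normalized posterior implied by the bias computation sums to 1
        prior = analytic_pitch_prior(SimConfig())
        noise = NoiseModel(kind="shear", sigma=0.1, additive_sd=2.3)
        theta = 20.0
        sd = likelihood_sd(theta, noise)
        lik = np.exp(-0.5 * ((prior.grid - theta) / sd) ** 2)
        post = lik * prior.density
        post = post / (post.sum() * prior.step)
        assert post.sum() * prior.step == pytest.approx(1.0, abs=1e-9)


class TestRse:
    def test_zero_when_prediction_matches(self):
        prior = gaussian_prior()
        noise = NoiseModel(kind="linear", sigma=0.1)
        curve = predict_bias_curve(prior, noise)
        angles = np.array([-30.0, 0.0, 30.0])
        obs = PsychBiasTable(angles=angles, observed_bias=curve.at(angles))
        assert rse(obs, curve) == 0.0

    def test_printed_example(self):
        from headstats.perception import BiasCurve
        curve_angles = np.array([1.0, 2.0, 3.0])
        pred = BiasCurve(angles=curve_angles, bias=np.array([1.0, 1.0, 1.0]))
        obs = PsychBiasTable(angles=curve_angles,
                             observed_bias=np.array([1.0, 2.0, 3.0]))
        assert rse(obs, pred) == pytest.approx(np.sqrt(5.0))

    def test_homogeneity(self):
        from headstats.perception import BiasCurve
        angles = np.arange(-5.0, 6.0)
        pred = BiasCurve(angles=angles, bias=np.zeros(len(angles)))
        resid = np.linspace(-1, 1, len(angles))
        a = rse(PsychBiasTable(angles=angles, observed_bias=resid), pred)
        b = rse(PsychBiasTable(angles=angles, observed_bias=2 * resid), pred)
        assert b == pytest.approx(2 * a)

    def test_too_few_points(self):
        from headstats.perception import BiasCurve
        pred = BiasCurve(angles=np.array([0.0, 1.0]), bias=np.zeros(2))
        obs = PsychBiasTable(angles=np.array([0.0, 1.0]),
                             observed_bias=np.zeros(2))
        with pytest.raises(ValueError, match="3 points"):
            rse(obs, pred)


class TestFitSigma:
    def test_noise_free_self_consistency(self):
        prior = analytic_pitch_prior(SimConfig())
        truth = NoiseModel(kind="shear", sigma=0.10, additive_sd=2.3)
        angles = np.arange(-90.0, 91.0, 15.0)
        table = simulate_psych_bias(prior, truth, angles, 0.0, seed=1)
        fit = fit_sigma(prior, table, "shear", additive_sd=2.3)
        assert fit.sigma_hat == pytest.approx(0.10, abs=1e-3)
        assert fit.rse < 1e-6

    def test_fit_is_deterministic(self):
        prior = analytic_pitch_prior(SimConfig())
        truth = NoiseModel(kind="linear", sigma=0.05, additive_sd=2.3)
        table = simulate_psych_bias(prior, truth, np.arange(-60.0, 61.0, 10.0),
                                    0.3, seed=5)
        a = fit_sigma(prior, table, "linear")
        b = fit_sigma(prior, table, "linear")
        assert a.sigma_hat == b.sigma_hat and a.rse == b.rse

    def test_invalid_bounds(self):
        prior = analytic_pitch_prior(SimConfig())
        table = PsychBiasTable(angles=np.array([-10.0, 0.0, 10.0]),
                               observed_bias=np.zeros(3))
        with pytest.raises(ValueError, match="bounds"):
            fit_sigma(prior, table, "linear", bounds=(0.5, 0.1))
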