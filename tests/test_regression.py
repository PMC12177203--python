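"""Joint MLE, posterior approximation and prediction for the copula regression."""

import numpy as np
import pytest

from fcgam.copula import FrankDependence
from fcgam.ratio import GammaMarginal, RatioLaw, joint_logpdf, ratio_cdf, ratio_quantile
from fcgam.regression import (CoefficientVector, ModelSpec, PairedDataset,
                              credible_intervals, fit_mle, log_likelihood,
                              predict_ratio_law, sample_posterior)
from fcgam.simulate import SimConfig, simulate_dataset

STUDY1_TRUTH = dict(beta_u=np.array([0.0, 0.4, -0.4, 0.2, -0.2]),
                    beta_v=np.array([0.0, -0.2, 0.2, -0.4, 0.4]))


def _intercept_only_gamma(theta=2.0, shapes=(2.0, 3.0), rates=(1.5, 0.7)):
    return CoefficientVector(
        beta_u=np.array([np.log(rates[0])]), beta_v=np.array([np.log(rates[1])]),
        beta_theta=np.array([theta]), shape_u=shapes[0], shape_v=shapes[1])


class TestLogLikelihood:
    def test_single_observation_reduces_to_joint_density(self):
        gamma = _intercept_only_gamma()
        data = PairedDataset(u=np.array([1.7]), v=np.array([2.4]),
                             covariates=np.empty((1, 0)))
        spec = ModelSpec(covariate_names=(), theta_mode="constant")
        expected = joint_logpdf(1.7, 2.4, GammaMarginal(1.5, 2.0),
                                GammaMarginal(0.7, 3.0), 2.0)
        assert log_likelihood(gamma, data, spec) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_row_order(self, study1_data):
        data, _ = study1_data
        spec = data.default_spec("constant")
        gamma = CoefficientVector(**STUDY1_TRUTH, beta_theta=np.array([-1.0]),
                                  shape_u=2.0, shape_v=6.0)
        perm = np.random.default_rng(0).permutation(data.n)
        shuffled = PairedDataset(u=data.u[perm], v=data.v[perm],
                                 covariates=data.covariates[perm],
                                 covariate_names=data.covariate_names)
        assert log_likelihood(gamma, shuffled, spec) == pytest.approx(
            log_likelihood(gamma, data, spec), rel=1e-12)

    def test_truth_beats_perturbations(self):
        data, _ = simulate_dataset(SimConfig.study1(-1.0, n=4000, seed=11))
        spec = data.default_spec("constant")
        gamma = CoefficientVector(**STUDY1_TRUTH, beta_theta=np.array([-1.0]),
                                  shape_u=2.0, shape_v=6.0)
        base = log_likelihood(gamma, data, spec)
        for block, idx in (("beta_u", 1), ("beta_v", 2)):
            kw = {k: v.copy() for k, v in STUDY1_TRUTH.items()}
            kw[block][idx] += 0.5
            worse = CoefficientVector(**kw, beta_theta=np.array([-1.0]),
                                      shape_u=2.0, shape_v=6.0)
            assert log_likelihood(worse, data, spec) < base

    def test_dimension_mismatch_raises(self, study1_data):
        data, _ = study1_data
        spec = data.default_spec("covariate")
        gamma = CoefficientVector(**STUDY1_TRUTH, beta_theta=np.array([-1.0]),
                                  shape_u=2.0, shape_v=6.0)  # constant-length theta
        with pytest.raises(ValueError):
            log_likelihood(gamma, data, spec)


class TestFitMle:
    def test_recovers_study1_coefficients(self, study1_fit):
        est = study1_fit.estimate
        # MC standard errors at n=500 are ~0.04; allow 4x that
        np.testing.assert_allclose(est.beta_u[1:], STUDY1_TRUTH["beta_u"][1:], atol=0.16)
        np.testing.assert_allclose(est.beta_v[1:], STUDY1_TRUTH["beta_v"][1:], atol=0.16)
        assert est.shape_u > 1.0 and est.shape_v > 1.0
        assert study1_fit.converged

    @pytest.mark.parametrize("theta0", [5.0, -5.0])
    def test_association_sign_recovery(self, theta0):
        cfg = SimConfig.study1(theta0, n=800, seed=3) if theta0 < 0 else \
            SimConfig.study2(theta0, n=800, seed=3)
        data, _ = simulate_dataset(cfg)
        fit = fit_mle(data, data.default_spec("constant"), seed=3)
        assert np.sign(fit.estimate.beta_theta[0]) == np.sign(theta0)
        assert abs(fit.estimate.beta_theta[0]) > 1.0

    def test_shape_constraint_enforced(self, study1_fit):
        assert study1_fit.estimate.shape_u > 1.0
        assert study1_fit.estimate.shape_v > 1.0

    def test_bic_definition(self, study1_fit):
        k, n = study1_fit.n_params, study1_fit.n_obs
        assert study1_fit.bic == pytest.approx(k * np.log(n) - 2 * study1_fit.loglik)

    def test_lambda_coefficients_invariant_to_common_rescaling(self, study1_data):
        # (u, v) -> (cu, cv) leaves Lambda slopes unchanged (absorbed by intercepts)
        data, _ = study1_data
        c = 7.3
        scaled = PairedDataset(u=c * data.u, v=c * data.v, covariates=data.covariates,
                               covariate_names=data.covariate_names)
        fit_a = fit_mle(data, data.default_spec("constant"), seed=1)
        fit_b = fit_mle(scaled, scaled.default_spec("constant"), seed=1)
        np.testing.assert_allclose(fit_a.estimate.lambda_coefficients[1:],
                                   fit_b.estimate.lambda_coefficients[1:], atol=5e-3)

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=(60, 2))
        x = np.column_stack([x, x[:, 0]])
        data = PairedDataset(u=rng.gamma(2.0, size=60) + 0.1,
                             v=rng.gamma(2.0, size=60) + 0.1, covariates=x)
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            fit_mle(data, data.default_spec("constant"))

    def test_too_few_observations_rejected(self, rng):
        data = PairedDataset(u=rng.gamma(2.0, size=8) + 0.1,
                             v=rng.gamma(2.0, size=8) + 0.1,
                             covariates=rng.normal(size=(8, 4)))
        with pytest.raises(ValueError, match="observations"):
            fit_mle(data, data.default_spec("constant"))


class TestPosterior:
    def test_mean_converges_to_mle(self, study1_fit):
        draws = sample_posterior(study1_fit, n_draws=100000, seed=5)
        cov = np.linalg.inv(study1_fit.hessian)
        se = np.sqrt(np.diag(cov)) / np.sqrt(draws.n_draws)
        mean_beta = draws.draws[:, :11].mean(axis=0)
        np.testing.assert_array_less(
            np.abs(mean_beta - study1_fit.optim_vector[:11]), 4 * se[:11] + 1e-12)

    def test_covariance_matches_inverse_information(self, study1_fit):
        draws = sample_posterior(study1_fit, n_draws=100000, seed=5)
        # compare on the sampling (optimization) scale for the beta block
        emp = np.cov(draws.draws[:, :11].T)
        target = np.linalg.inv(study1_fit.hessian)[:11, :11]
        assert np.linalg.norm(emp - target) < 0.05 * np.linalg.norm(target)

    def test_seed_determinism(self, study1_fit):
        a = sample_posterior(study1_fit, n_draws=2000, seed=42)
        b = sample_posterior(study1_fit, n_draws=2000, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_minimum_draws_enforced(self, study1_fit):
        with pytest.raises(ValueError):
            sample_posterior(study1_fit, n_draws=500, seed=1)


class TestCredibleIntervals:
    def test_percentile_convention(self, study1_fit):
        draws = sample_posterior(study1_fit, n_draws=10000, seed=9)
        table = credible_intervals(draws, level=0.95)
        col = draws.column("beta_u[x1]")
        lo, hi = np.quantile(col, [0.025, 0.975])
        row = table.loc["beta_u[x1]"]
        assert row["lower"] == pytest.approx(lo) and row["upper"] == pytest.approx(hi)

    def test_lambda_interval_from_differenced_draws(self, study1_fit):
        draws = sample_posterior(study1_fit, n_draws=10000, seed=9)
        table = credible_intervals(draws, level=0.95)
        diff = draws.column("beta_u[x1]") - draws.column("beta_v[x1]")
        lo, hi = np.quantile(diff, [0.025, 0.975])
        row = table.loc["beta_lambda[x1]"]
        assert row["lower"] == pytest.approx(lo) and row["upper"] == pytest.approx(hi)
        # NOT the difference of the individual interval endpoints
        naive = (table.loc["beta_u[x1]", "lower"] - table.loc["beta_v[x1]", "lower"])
        assert abs(row["lower"] - naive) > 1e-6

    def test_transform_hook(self, study1_fit):
        draws = sample_posterior(study1_fit, n_draws=10000, seed=9)
        table = credible_intervals(
            draws, transform=lambda m: {"shape_sum": m[:, -2] + m[:, -1]})
        assert "shape_sum" in table.index

    def test_invalid_level(self, study1_fit):
        draws = sample_posterior(study1_fit, n_draws=2000, seed=9)
        with pytest.raises(ValueError):
            credible_intervals(draws, level=1.2)


class TestPrediction:
    def test_intercept_only_reduction(self, study1_fit):
        law = predict_ratio_law(study1_fit, np.zeros(4))
        est = study1_fit.estimate
        assert law.lambda_ratio == pytest.approx(np.exp(est.beta_u[0] - est.beta_v[0]))
        assert law.theta == pytest.approx(est.beta_theta[0])

    def test_constant_theta_across_profiles(self, study1_fit):
        thetas = {predict_ratio_law(study1_fit, x).theta
                  for x in (np.zeros(4), np.array([1.0, -1.0, 1.0, 0.0]))}
        assert len(thetas) == 1

    def test_predicted_median_dual_path(self, study1_fit):
        # quantile inversion vs direct integration of the predicted pdf
        law = predict_ratio_law(study1_fit, np.array([0.5, -0.5, 1.0, 0.0]))
        med = ratio_quantile(0.5, law)
        from scipy.integrate import quad
        from fcgam.ratio import ratio_pdf
        mass, _ = quad(lambda r: ratio_pdf(r, law), 1e-9, med, limit=200)
        assert mass == pytest.approx(0.5, abs=1e-5)

    def test_wrong_profile_dimension(self, study1_fit):
        with pytest.raises(ValueError):
            predict_ratio_law(study1_fit, np.zeros(3))
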