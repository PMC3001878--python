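"""Experimenter-level inversion: recovery, evidence, diagnostics, serialization."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from metabayes import (
    InversionOptions,
    ParameterPrior,
    SimulationConfig,
    ToyObserverConfig,
    TrialData,
    compare_models,
    identifiability_report,
    invert,
    reconstruct_subject_belief,
    response_free_energy,
    simulate_observer,
    toy_perceptual_model,
    toy_response_model,
)
from metabayes.decision import ResponseModelSpec
from metabayes.errors import IllPosedError, InvalidInputError
from metabayes.inversion import ExperimenterPosterior
from metabayes.recognition import PerceptualModelSpec


def dummy_perceptual(n_theta=1):
    """Placeholder perceptual model for fast-path-only linear response models."""
    return PerceptualModelSpec(
        log_prior=lambda x, th: -0.5 * x[0] ** 2,
        log_likelihood=lambda u, x, th: 0.0,
        state_dim=1,
        theta_names=tuple(f"t{i}" for i in range(n_theta)),
    )


def linear_response(A, sigma2):
    """Response model predicting A @ eta per 'trial' (rows of A), Gaussian noise."""
    A = np.asarray(A, dtype=float)

    def predict(theta, phi, data):
        eta = np.concatenate([theta, phi])
        return (A @ eta).reshape(-1, 1)

    return ResponseModelSpec(
        loss=None,
        observation_map=lambda b, phi: None,
        residual_covariance=np.array([[sigma2]]),
        response_dim=1,
        phi_names=("p0",),
        predict_fast=predict,
    )


class TestInvertToy:
    def test_recovers_generating_parameters(self, wide_prior):
        obs = ToyObserverConfig(beta=1.0, k=0.01, sigma2=0.01**2)
        data = simulate_observer(SimulationConfig(observer=obs, n_trials=100, seed=42))
        perc, resp = toy_perceptual_model(), toy_response_model(obs)
        post = invert(perc, resp, data, wide_prior,
                      InversionOptions(seed=0, store_beliefs=False))
        truth = np.array([np.log(1.0), np.log(0.01)])
        err = np.abs(post.mode - truth)
        sd = post.posterior_sd()
        assert np.all(err <= 3.0 * sd + 1e-12)
        assert err[0] <= 0.1 * max(abs(truth[0]), 1.0)
        assert err[1] <= 0.1 * abs(truth[1])

    def test_all_missing_responses_return_the_prior(self, toy_models, wide_prior,
                                                    fast_options):
        perc, resp = toy_models
        T = 5
        data = TrialData(inputs=[np.zeros(3)] * T,
                         responses=[np.full(2, np.nan)] * T)
        post = invert(perc, resp, data, wide_prior, fast_options)
        np.testing.assert_allclose(post.mode, wide_prior.mean, atol=1e-6)
        np.testing.assert_allclose(post.covariance, wide_prior.covariance, rtol=1e-6)

    def test_free_energy_recomputation_matches(self, toy_models, toy_data,
                                               wide_prior, fast_options):
        perc, resp = toy_models
        post = invert(perc, resp, toy_data, wide_prior, fast_options)
        assert response_free_energy(post, wide_prior) == pytest.approx(
            post.free_energy, abs=1e-9)

    def test_trial_order_invariance_of_free_energy(self, toy_models, toy_data,
                                                   wide_prior, fast_options):
        perc, resp = toy_models
        post1 = invert(perc, resp, toy_data, wide_prior, fast_options)
        rng = np.random.default_rng(0)
        order = rng.permutation(toy_data.n_trials)
        shuffled = TrialData(inputs=[toy_data.inputs[i] for i in order],
                             responses=[toy_data.responses[i] for i in order])
        post2 = invert(perc, resp, shuffled, wide_prior, fast_options)
        assert post1.free_energy == pytest.approx(post2.free_energy, abs=1e-8)

    def test_posterior_sd_shrinks_with_more_trials(self, toy_config, wide_prior):
        perc, resp = toy_perceptual_model(), toy_response_model(toy_config)
        mean_sd = []
        for T in (25, 200):
            sds = []
            for seed in range(3):
                data = simulate_observer(
                    SimulationConfig(observer=toy_config, n_trials=T, seed=seed))
                post = invert(perc, resp, data, wide_prior,
                              InversionOptions(n_starts=2, seed=seed,
                                               store_beliefs=False))
                sds.append(post.posterior_sd())
            mean_sd.append(np.mean(sds, axis=0))
        assert np.all(mean_sd[1] < mean_sd[0])

    def test_estimated_noise_recovers_residual_variance(self, toy_config):
        data = simulate_observer(
            SimulationConfig(observer=toy_config, n_trials=150, seed=3))
        perc = toy_perceptual_model()
        resp = toy_response_model(toy_config)
        resp.residual_covariance = "estimated"
        prior = ParameterPrior(mean=np.zeros(2), covariance=np.diag([100.0, 100.0]),
                               noise_hyperprior=(1e-3, 1e-3))
        post = invert(perc, resp, data, prior,
                      InversionOptions(n_starts=2, seed=0, store_beliefs=False,
                                       sigma2_init=0.1))
        assert post.noise_variance == pytest.approx(toy_config.sigma2, rel=0.4)

    def test_ill_posed_without_proper_priors(self, toy_models):
        perc, resp = toy_models
        data = TrialData(inputs=[np.zeros(2)],
                         responses=[np.array([0.1, np.nan])])
        prior = ParameterPrior(mean=np.zeros(2), covariance=np.diag([1e12, 1e12]))
        with pytest.raises(IllPosedError):
            invert(perc, resp, data, prior)


class TestLinearGaussianExactness:
    """With a linear prediction map the Laplace treatment is exact."""

    def setup_method(self):
        rng = np.random.default_rng(8)
        self.A = rng.standard_normal((12, 2))
        self.sigma2 = 0.3
        eta_true = np.array([0.4, -0.6])
        self.y = self.A @ eta_true + np.sqrt(self.sigma2) * rng.standard_normal(12)
        self.data = TrialData(inputs=[np.zeros(1)] * 12,
                              responses=[np.array([v]) for v in self.y])
        self.prior = ParameterPrior(mean=np.zeros(2), covariance=np.diag([4.0, 4.0]))
        self.perc = dummy_perceptual()
        self.resp = linear_response(self.A, self.sigma2)
        self.options = InversionOptions(n_starts=1, store_beliefs=False)

    def test_free_energy_equals_exact_log_evidence(self):
        post = invert(self.perc, self.resp, self.data, self.prior, self.options)
        marginal_cov = self.sigma2 * np.eye(12) + self.A @ self.prior.covariance @ self.A.T
        exact = multivariate_normal.logpdf(self.y, mean=np.zeros(12), cov=marginal_cov)
        assert post.free_energy == pytest.approx(exact, abs=1e-7)

    def test_posterior_covariance_never_exceeds_prior(self):
        post = invert(self.perc, self.resp, self.data, self.prior, self.options)
        gap_eigs = np.linalg.eigvalsh(self.prior.covariance - post.covariance)
        assert np.all(gap_eigs >= -1e-9)

    def test_delta_prior_limit_reduces_to_loglik_at_truth(self):
        pinned = ParameterPrior(mean=np.array([0.4, -0.6]),
                                covariance=np.diag([1e-12, 1e-12]))
        post = invert(self.perc, self.resp, self.data, pinned, self.options)
        r = self.y - self.A @ pinned.mean
        loglik = float(-0.5 * r @ r / self.sigma2
                       - 6.0 * np.log(2 * np.pi * self.sigma2))
        assert post.free_energy == pytest.approx(loglik, abs=1e-4)


class TestModelComparison:
    def test_duplicated_candidate_splits_probability(self, toy_models, toy_data,
                                                     wide_prior, fast_options):
        perc, resp = toy_models
        result = compare_models([(perc, resp, wide_prior)] * 2, toy_data, fast_options)
        np.testing.assert_allclose(result.posterior_model_probabilities,
                                   [0.5, 0.5], atol=1e-6)

    def test_identical_pair_plus_misspecified_candidate(self, toy_config, toy_data,
                                                        wide_prior, fast_options):
        perc, resp = toy_perceptual_model(), toy_response_model(toy_config)
        pinned_bad = ParameterPrior(mean=np.array([np.log(1e-2), 0.0]),
                                    covariance=np.diag([1e-6, 100.0]))
        result = compare_models(
            [(perc, resp, wide_prior), (perc, resp, wide_prior),
             (perc, resp, pinned_bad)],
            toy_data, fast_options)
        p = result.posterior_model_probabilities
        assert p[0] == pytest.approx(p[1], abs=1e-6)
        assert p[2] < p[0]
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_redundant_parameter_pays_an_occam_penalty(self, wide_prior):
        obs = ToyObserverConfig(beta=2.0, k=0.01, sigma2=0.05**2)
        perc = toy_perceptual_model()
        base = toy_response_model(obs)
        wins_for_augmented = 0
        for seed in range(5):
            data = simulate_observer(
                SimulationConfig(observer=obs, n_trials=80, seed=seed))
            augmented = toy_response_model(obs)
            base_predict = base.predict_fast

            def predict_aug(theta, phi, data, _bp=base_predict):
                out = _bp(theta, phi[:1], data)
                out = out.copy()
                out[:, 0] += phi[1]  # redundant additive report bias
                return out

            augmented.phi_names = ("k", "bias")
            augmented.phi_transform = ("exp", "identity")
            augmented.predict_fast = predict_aug
            prior3 = ParameterPrior(mean=np.zeros(3),
                                    covariance=np.diag([100.0, 100.0, 100.0]))
            options = InversionOptions(n_starts=2, seed=seed, store_beliefs=False)
            f_base = invert(perc, base, data, wide_prior, options).free_energy
            f_aug = invert(perc, augmented, data, prior3, options).free_energy
            wins_for_augmented += int(f_aug > f_base)
        assert wins_for_augmented <= 1


class TestSubjectBeliefReconstruction:
    def test_zero_noise_limit_returns_subject_variance(self, toy_config, wide_prior):
        obs = ToyObserverConfig(beta=2.0, k=0.01, sigma2=0.0)
        data = simulate_observer(SimulationConfig(observer=obs, n_trials=40, seed=1))
        assumed = ToyObserverConfig(beta=2.0, k=0.01, sigma2=1e-10)
        perc, resp = toy_perceptual_model(), toy_response_model(assumed)
        post = invert(perc, resp, data, wide_prior,
                      InversionOptions(n_starts=1, seed=0))
        mean, var, ci = reconstruct_subject_belief(post, perc, data, trial=0)
        subj = post.belief_trajectory_at_mode[0]
        assert var[0, 0] == pytest.approx(subj.covariance[0, 0], abs=1e-6)

    def test_inflated_interval_contains_subject_interval(self, toy_models, toy_data,
                                                         wide_prior):
        perc, resp = toy_models
        post = invert(perc, resp, toy_data, wide_prior,
                      InversionOptions(n_starts=2, seed=0))
        mean, var, (lo, hi) = reconstruct_subject_belief(post, perc, toy_data, trial=2)
        subj = post.belief_trajectory_at_mode[2]
        z = 1.6449
        subj_sd = np.sqrt(subj.covariance[0, 0])
        assert var[0, 0] >= subj.covariance[0, 0] - 1e-12
        assert lo[0] <= mean[0] - z * subj_sd + 1e-9
        assert hi[0] >= mean[0] + z * subj_sd - 1e-9

    def test_trial_out_of_range(self, toy_models, toy_data, wide_prior, fast_options):
        perc, resp = toy_models
        post = invert(perc, resp, toy_data, wide_prior, fast_options)
        with pytest.raises(IndexError):
            reconstruct_subject_belief(post, perc, toy_data, trial=toy_data.n_trials)


class TestIdentifiability:
    def test_diagonal_covariance_has_no_flags(self):
        post = ExperimenterPosterior(
            mode=np.zeros(2), covariance=np.diag([0.2, 0.5]), free_energy=0.0,
            residuals=[], noise_variance=1.0, belief_trajectory_at_mode=None,
            param_names=("a", "b"), loglik=0.0, hyper_log_prior=0.0,
            prior_mean=np.zeros(2), prior_covariance=np.eye(2))
        report = identifiability_report(post)
        assert report.flagged_pairs == []
        np.testing.assert_allclose(report.correlation, np.eye(2), atol=1e-12)

    def test_confounded_parameters_are_flagged(self):
        """A map depending only on theta+phi leaves the difference unidentified."""
        rng = np.random.default_rng(2)
        col = np.ones((15, 1))
        A = np.column_stack([col, col])  # predictions depend on eta0 + eta1 only
        y = 0.7 + 0.05 * rng.standard_normal(15)
        data = TrialData(inputs=[np.zeros(1)] * 15,
                         responses=[np.array([v]) for v in y])
        post = invert(dummy_perceptual(), linear_response(A, 0.05**2), data,
                      ParameterPrior(mean=np.zeros(2), covariance=np.diag([25.0, 25.0])),
                      InversionOptions(n_starts=1, store_beliefs=False))
        report = identifiability_report(post)
        assert len(report.flagged_pairs) == 1
        assert abs(report.flagged_pairs[0][2]) > 0.95

    def test_zero_variance_parameter_reported_degenerate(self):
        post = ExperimenterPosterior(
            mode=np.zeros(2), covariance=np.diag([0.0, 0.5]), free_energy=0.0,
            residuals=[], noise_variance=1.0, belief_trajectory_at_mode=None,
            param_names=("a", "b"), loglik=0.0, hyper_log_prior=0.0,
            prior_mean=np.zeros(2), prior_covariance=np.eye(2))
        report = identifiability_report(post)
        assert report.degenerate == ["a"]


class TestSerialization:
    def test_posterior_json_round_trip(self, toy_models, toy_data, wide_prior,
                                       tmp_path):
        perc, resp = toy_models
        post = invert(perc, resp, toy_data, wide_prior,
                      InversionOptions(n_starts=1, seed=0))
        path = tmp_path / "posterior.json"
        post.to_json(path)
        back = ExperimenterPosterior.from_json(path)
        np.testing.assert_array_equal(back.mode, post.mode)
        np.testing.assert_array_equal(back.covariance, post.covariance)
        assert back.free_energy == post.free_energy
        assert back.param_names == list(post.param_names)
        assert len(back.residuals) == len(post.residuals)
        for a, b in zip(back.residuals, post.residuals):
            np.testing.assert_array_equal(a, b)
        assert len(back.belief_trajectory_at_mode) == len(post.belief_trajectory_at_mode)
        b0, p0 = back.belief_trajectory_at_mode[0], post.belief_trajectory_at_mode[0]
        np.testing.assert_array_equal(b0.mode, p0.mode)
        assert back.settings == post.settings

    def test_dimension_mismatch_rejected(self, toy_models, toy_data, wide_prior,
                                         fast_options):
        perc, resp = toy_models
        post = invert(perc, resp, toy_data, wide_prior, fast_options)
        bad_prior = ParameterPrior(mean=np.zeros(3), covariance=np.eye(3))
        with pytest.raises(InvalidInputError):
            response_free_energy(post, bad_prior)
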