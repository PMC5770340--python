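"""Variational Gaussian mixture: E/M steps, missing data, weights, priors."""

import numpy as np
import pytest
from scipy.special import logsumexp

from genatlas import intensity as intens


def _simple_posterior(K=2, D=1, seed=0):
    rng = np.random.default_rng(seed)
    m = rng.normal(0, 1, (K, D))
    beta = np.full(K, 4.0)
    W = np.stack([np.eye(D) * 2.0] * K)
    nu = np.full(K, D + 3.0)
    return intens.MixturePosterior(m, beta, W, nu)


class TestEStep:
    def test_symmetric_densities_give_uniform(self):
        K = 4
        log_dens = np.zeros((5, K))
        log_prior = np.full((5, K), np.log(1.0 / K))
        gamma = intens.e_step_unsupervised(log_dens, log_prior)
        np.testing.assert_allclose(gamma, 1.0 / K)

    def test_bayes_rule_ratio(self):
        log_dens = np.log(np.array([[3.0, 1.0]]))
        log_prior = np.log(np.array([[0.5, 0.5]]))
        gamma = intens.e_step_unsupervised(log_dens, log_prior)
        np.testing.assert_allclose(gamma, [[0.75, 0.25]], atol=1e-12)

    def test_matches_direct_density_evaluation(self):
        """Tiny case N=4, K=2, D=1: responsibilities equal a brute-force
        evaluation of the posterior with explicit expected log-densities."""
        rng = np.random.default_rng(1)
        post = _simple_posterior()
        x = rng.normal(0, 1, (4, 1))
        prior_probs = rng.dirichlet((1, 1), size=4)
        log_dens = intens.expected_log_densities(x, post)
        gamma = intens.e_step_unsupervised(log_dens, np.log(prior_probs))
        # independent direct evaluation (scalar loop, explicit formulas)
        from scipy.special import digamma

        expected = np.zeros((4, 2))
        for n in range(4):
            logr = np.zeros(2)
            for k in range(2):
                elogdet = digamma(post.nu[k] / 2) + np.log(2) + np.log(post.W[k, 0, 0])
                quad = post.nu[k] * post.W[k, 0, 0] * (x[n, 0] - post.m[k, 0]) ** 2
                e = 0.5 * (elogdet - np.log(2 * np.pi) - 1 / post.beta[k] - quad)
                logr[k] = e + np.log(prior_probs[n, k])
            expected[n] = np.exp(logr - logsumexp(logr))
        np.testing.assert_allclose(gamma, expected, atol=1e-12)

    def test_underflow_resolved_in_log_domain(self):
        log_dens = np.array([[-2000.0, -2001.0]])
        log_prior = np.log(np.array([[0.5, 0.5]]))
        gamma = intens.e_step_unsupervised(log_dens, log_prior)
        assert np.isfinite(gamma).all()
        assert gamma.sum() == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        gamma = intens.e_step_unsupervised(
            rng.normal(size=(50, 3)), np.log(rng.dirichlet(np.ones(3), 50))
        )
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def test_no_evidence_leaves_prior(self):
        prior = intens.GaussWishartPrior([[0.0], [1.0]], [1.0, 1.0],
                                         [np.eye(1), np.eye(1)], [3.0, 3.0])
        Nk = np.array([5.0, 0.0])
        s1 = np.array([[10.0], [0.0]])
        S2 = np.array([[[25.0]], [[0.0]]])
        post = intens.m_step(Nk, s1, S2, prior)
        assert post.m[1, 0] == pytest.approx(1.0)
        assert post.beta[1] == pytest.approx(1.0)
        assert post.nu[1] == pytest.approx(3.0)

    def test_single_voxel_conjugate_arithmetic(self):
        prior = intens.GaussWishartPrior([[0.0]], [1.0], [np.eye(1)], [3.0])
        post = intens.m_step(np.array([1.0]), np.array([[2.0]]),
                             np.array([[[4.0]]]), prior)
        assert post.m[0, 0] == pytest.approx(1.0)
        assert post.beta[0] == pytest.approx(2.0)

    def test_matches_hand_coded_conjugate_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.5, 0.7, (10, 1))
        gamma = rng.dirichlet((2, 1), size=10)
        prior = intens.GaussWishartPrior([[0.0], [1.0]], [0.5, 2.0],
                                         [np.eye(1) * 2, np.eye(1)], [2.5, 4.0])
        Nk, s1, S2 = intens.sufficient_statistics(x, gamma)
        post = intens.m_step(Nk, s1, S2, prior)
        for k in range(2):
            N = gamma[:, k].sum()
            xbar = (gamma[:, k] @ x[:, 0]) / N
            S = (gamma[:, k] @ (x[:, 0] - xbar) ** 2) / N
            beta = prior.beta0[k] + N
            m = (prior.beta0[k] * prior.m0[k, 0] + N * xbar) / beta
            Winv = (
                1 / prior.W0[k, 0, 0]
                + N * S
                + prior.beta0[k] * N / beta * (xbar - prior.m0[k, 0]) ** 2
            )
            assert post.beta[k] == pytest.approx(beta, abs=1e-12)
            assert post.nu[k] == pytest.approx(prior.nu0[k] + N, abs=1e-12)
            assert post.m[k, 0] == pytest.approx(m, abs=1e-12)
            assert post.W[k, 0, 0] == pytest.approx(1 / Winv, abs=1e-12)

    def test_flat_prior_recovers_ml_gmm(self):
        """With a nearly flat prior the VB M-step matches classical EM."""
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.5, 150), rng.normal(2, 0.5, 150)])[:, None]
        K = 2
        prior = intens.GaussWishartPrior(
            np.zeros((K, 1)), np.full(K, 1e-10), np.stack([np.eye(1) * 1e10] * K),
            np.full(K, 1e-4),
        )
        # classical EM oracle
        mu = np.array([-1.0, 1.0])
        var = np.array([1.0, 1.0])
        pi_k = np.array([0.5, 0.5])
        for _ in range(200):
            logp = (
                -0.5 * (x - mu) ** 2 / var - 0.5 * np.log(2 * np.pi * var) + np.log(pi_k)
            )
            g = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
            N = g.sum(axis=0)
            mu = (g * x).sum(axis=0) / N
            var = (g * (x - mu) ** 2).sum(axis=0) / N
            pi_k = N / N.sum()
        # VB with the same responsibilities
        Nk, s1, S2 = intens.sufficient_statistics(x, g)
        post = intens.m_step(Nk, s1, S2, prior)
        np.testing.assert_allclose(post.m[:, 0], mu, atol=1e-6)
        np.testing.assert_allclose(
            1.0 / (post.nu * post.W[:, 0, 0]), var, rtol=1e-6
        )

    def test_posterior_spd_and_nu_grows(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 3))
        gamma = rng.dirichlet(np.ones(2), 30)
        prior = intens.GaussWishartPrior(
            np.zeros((2, 3)), np.ones(2), np.stack([np.eye(3)] * 2), np.full(2, 5.0)
        )
        Nk, s1, S2 = intens.sufficient_statistics(x, gamma)
        post = intens.m_step(Nk, s1, S2, prior)
        for k in range(2):
            np.linalg.cholesky(post.W[k])
            assert post.nu[k] >= prior.nu0[k]


class TestMissingData:
    def test_reduces_to_complete_data(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 2))
        gamma = rng.dirichlet(np.ones(2), 20)
        post = _simple_posterior(K=2, D=2)
        obs = np.ones((20, 2), dtype=bool)
        a = intens.missing_data_statistics(x, obs, gamma, post)
        b = intens.sufficient_statistics(x, gamma)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_independent_channels_impute_prior_mean(self):
        post = intens.MixturePosterior(
            np.zeros((1, 2)), np.full(1, 1e12), [np.eye(2) / 2.5], [2.5]
        )  # E[Lambda] = nu W = I -> cov I
        x = np.array([[0.7, np.nan]])
        obs = np.array([[True, False]])
        gamma = np.ones((1, 1))
        Nk, s1, S2 = intens.missing_data_statistics(
            np.nan_to_num(x), obs, gamma, post
        )
        assert s1[0, 1] == pytest.approx(0.0)          # imputed prior mean
        assert S2[0, 1, 1] == pytest.approx(1.0)       # conditional variance
        assert s1[0, 0] == pytest.approx(0.7)

    def test_matches_monte_carlo_imputation(self):
        """Correlated D=2 class: augmented statistics agree with Monte-Carlo
        imputation of the missing channel within 3 standard errors."""
        rng = np.random.default_rng(7)
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        prec = np.linalg.inv(cov)
        post = intens.MixturePosterior(
            np.array([[0.5, -0.5]]), np.full(1, 1e12), [prec / 2.5], [2.5]
        )
        x1 = 1.3
        x = np.array([[x1, 0.0]])
        obs = np.array([[True, False]])
        gamma = np.ones((1, 1))
        _, s1, S2 = intens.missing_data_statistics(x, obs, gamma, post)
        n = 1_000_000
        mu_c = -0.5 + 0.8 * (x1 - 0.5)
        var_c = 1.0 - 0.8**2
        draws = rng.normal(mu_c, np.sqrt(var_c), n)
        se_mean = np.sqrt(var_c / n)
        assert abs(s1[0, 1] - draws.mean()) < 3 * se_mean
        mc_second = (draws**2).mean()
        se_second = (draws**2).std() / np.sqrt(n)
        assert abs(S2[0, 1, 1] - mc_second) < 3 * se_second

    def test_all_missing_voxel_excluded(self):
        post = _simple_posterior(K=1, D=2)
        x = np.zeros((2, 2))
        obs = np.array([[True, True], [False, False]])
        gamma = np.ones((2, 1))
        Nk, _, _ = intens.missing_data_statistics(x, obs, gamma, post)
        assert Nk[0] == pytest.approx(1.0)


class TestMixingWeights:
    def test_stationary_at_match(self):
        rng = np.random.default_rng(8)
        p = rng.dirichlet(np.ones(3), 500)
        w = intens.update_mixing_weights(p.copy(), p)
        np.testing.assert_allclose(w, 1.0, atol=5e-3)

    def test_two_to_one_ratio_on_flat_template(self):
        N = 3000
        gamma = np.zeros((N, 2))
        gamma[: 2 * N // 3, 0] = 1.0
        gamma[2 * N // 3:, 1] = 1.0
        p = np.full((N, 2), 0.5)
        w = intens.update_mixing_weights(gamma, p)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-6)

    def test_scale_invariance_of_class_prior(self):
        from genatlas.template import TissueTemplate, warped_class_prior
        from genatlas.grids import VoxelGrid, identity_map

        rng = np.random.default_rng(9)
        probs = rng.dirichlet(np.ones(3), size=(4, 4, 4))
        tpl = TissueTemplate(VoxelGrid((4, 4, 4)), np.moveaxis(probs, -1, 0))
        pts = identity_map((4, 4, 4))
        w = np.array([0.5, 1.0, 2.0])
        a = warped_class_prior(tpl, pts, w)
        b = warped_class_prior(tpl, pts, 2.0 * w)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_returned_weights_positive_mean_one(self):
        rng = np.random.default_rng(10)
        gamma = rng.dirichlet(np.ones(4), 200)
        p = rng.dirichlet(np.ones(4), 200)
        w = intens.update_mixing_weights(gamma, p)
        assert (w > 0).all()
        assert w.mean() == pytest.approx(1.0)


class TestEmpiricalPriors:
    def _posteriors(self, means, seed=0):
        posts = []
        for m in means:
            posts.append(
                intens.MixturePosterior(np.array([[m]]), [50.0], [np.eye(1) * 0.5],
                                        [20.0])
            )
        return posts

    def test_identical_posteriors_concentrate(self):
        posts = self._posteriors([1.7, 1.7, 1.7])
        prior = intens.GaussWishartPrior([[0.0]], [1.0], [np.eye(1)], [3.0])
        new = intens.update_empirical_priors(posts, prior)
        assert new.m0[0, 0] == pytest.approx(1.7, abs=1e-8)

    def test_symmetric_means_give_zero(self):
        posts = self._posteriors([-1.0, 1.0])
        prior = intens.GaussWishartPrior([[0.0]], [1.0], [np.eye(1)], [3.0])
        new = intens.update_empirical_priors(posts, prior)
        assert new.m0[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_single_subject_returns_unchanged(self):
        posts = self._posteriors([2.0])
        prior = intens.GaussWishartPrior([[0.3]], [1.5], [np.eye(1)], [3.0])
        new = intens.update_empirical_priors(posts, prior)
        assert new.m0[0, 0] == pytest.approx(0.3)
        assert new.beta0[0] == pytest.approx(1.5)

    def test_local_optimality_against_random_perturbations(self):
        """Maximised empirical-Bayes objective beats 100 random perturbations
        of the returned hyperparameters on 5 simulated subject posteriors."""
        rng = np.random.default_rng(11)
        posts = []
        for _ in range(5):
            posts.append(
                intens.MixturePosterior(
                    rng.normal(1.0, 0.3, (1, 1)), [rng.uniform(20, 60)],
                    [np.eye(1) * rng.uniform(0.3, 0.8)], [rng.uniform(10, 30)],
                )
            )
        prior = intens.GaussWishartPrior([[0.0]], [1.0], [np.eye(1)], [3.0])
        new = intens.update_empirical_priors(posts, prior, n_sweeps=8)

        def objective(p):
            return sum(intens.expected_log_prior_density(q, p) for q in posts)

        base = objective(new)
        for _ in range(100):
            pert = new.copy()
            pert.m0 = new.m0 + rng.normal(0, 0.05, new.m0.shape)
            pert.beta0 = new.beta0 * np.exp(rng.normal(0, 0.05))
            pert.W0 = new.W0 * np.exp(rng.normal(0, 0.05))
            pert.nu0 = np.maximum(new.nu0 * np.exp(rng.normal(0, 0.05)), 1.0 + 1e-3)
            assert objective(pert) <= base + 1e-9
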