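"""Variational Laplace, PEB, BMR and model averaging against conjugate oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from affectpipe.dcm import peb as peb_mod
from affectpipe.dcm.invert import (SubjectPosterior, vl_core)
from affectpipe.dcm.peb import (bayesian_model_reduction, build_design_matrix,
                                greedy_prune_and_average, implied_observation,
                                peb_fit)


def make_linear_problem(seed=3, n=40, d=3, sigma=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    theta = rng.standard_normal(d)
    y = X @ theta + sigma * rng.standard_normal(n)
    S0 = np.diag([1.0, 2.0, 0.5])
    return X, y, S0, sigma


class TestVariationalLaplaceCore:
    def test_conjugate_linear_gaussian_oracle(self):
        """Posterior and F equal the closed form for a linear model."""
        X, y, S0, sigma = make_linear_problem()
        lam = np.log(1 / sigma ** 2)
        mean, cov, F, _, _ = vl_core(y, lambda th: X @ th, np.zeros(3), S0,
                                     estimate_noise=False,
                                     lambda_prior=(lam, 1.0),
                                     max_iter=50, tol=1e-10)
        prec = 1 / sigma ** 2
        P0 = np.linalg.inv(S0)
        Sig = np.linalg.inv(prec * X.T @ X + P0)
        mu = Sig @ (prec * X.T @ y)
        logev = multivariate_normal.logpdf(
            y, mean=np.zeros(len(y)), cov=sigma ** 2 * np.eye(len(y)) + X @ S0 @ X.T)
        assert np.abs(mean - mu).max() < 1e-6
        assert np.abs(cov - Sig).max() < 1e-6
        assert F == pytest.approx(logev, abs=1e-4)

    def test_free_energy_lower_bounds_evidence(self):
        X, y, S0, sigma = make_linear_problem(seed=9)
        lam = np.log(1 / sigma ** 2)
        _, _, F, _, _ = vl_core(y, lambda th: X @ th, np.zeros(3), S0,
                                estimate_noise=False, lambda_prior=(lam, 1.0),
                                max_iter=50, tol=1e-10)
        logev = multivariate_normal.logpdf(
            y, mean=np.zeros(len(y)), cov=sigma ** 2 * np.eye(len(y)) + X @ S0 @ X.T)
        assert F <= logev + 1e-4

    def test_uninformative_data_returns_prior(self):
        """With the noise precision pinned near zero the posterior is the prior."""
        X, y, S0, _ = make_linear_problem(seed=5)
        mean, cov, _, _, _ = vl_core(y, lambda th: X @ th, np.zeros(3), S0,
                                     estimate_noise=False,
                                     lambda_prior=(-30.0, 1.0), max_iter=20,
                                     tol=1e-10)
        assert np.abs(mean).max() < 1e-6
        assert np.abs(cov - S0).max() < 1e-5

    def test_noise_precision_recovered(self):
        X, y, S0, sigma = make_linear_problem(seed=11, n=400)
        _, _, _, lam, _ = vl_core(y, lambda th: X @ th, np.zeros(3), S0,
                                  estimate_noise=True,
                                  lambda_prior=(2.0, 2.0), max_iter=50,
                                  tol=1e-8)
        assert np.exp(-lam / 2) == pytest.approx(sigma, rel=0.15)


def make_subject_posterior(mean, cov, prior_var, names=None):
    d = len(mean)
    names = names or tuple(f"A.p{i}" for i in range(d))
    return SubjectPosterior(mean=np.asarray(mean, float),
                            cov=np.asarray(cov, float), free_energy=0.0,
                            log_precision=4.0, param_names=names,
                            prior_mean=np.zeros(d),
                            prior_cov=np.diag(prior_var))


class TestPebFit:
    def test_intercept_only_equals_precision_weighted_mean(self):
        """Homogeneous covariances, wide priors: beta = mean of subjects."""
        rng = np.random.default_rng(0)
        d = 2
        subj = [make_subject_posterior(rng.normal(0.3, 0.1, d),
                                       0.05 * np.eye(d), [1e6] * d)
                for _ in range(8)]
        X = np.ones((8, 1))
        res = peb_fit(subj, X, param_subset=np.arange(d),
                      beta_prior_scale=1.0, re_scale=1e8)
        target = np.mean([implied_observation(s, np.arange(d))[0]
                          for s in subj], axis=0)
        assert np.abs(res.beta_mean - target).max() < 1e-6

    def test_duplicating_subjects_shrinks_variance_keeps_mean(self):
        rng = np.random.default_rng(1)
        d = 2
        subj = [make_subject_posterior(rng.normal(0.2, 0.1, d),
                                       0.05 * np.eye(d), [10.0] * d)
                for _ in range(6)]
        X = np.ones((6, 1))
        res1 = peb_fit(subj, X, param_subset=np.arange(d))
        res2 = peb_fit(subj * 2, np.ones((12, 1)), param_subset=np.arange(d))
        assert np.abs(res1.beta_mean - res2.beta_mean).max() < 5e-3
        assert np.all(np.diag(res2.beta_cov) < np.diag(res1.beta_cov))

    def test_uncentered_covariates_rejected(self):
        rng = np.random.default_rng(2)
        subj = [make_subject_posterior(rng.normal(size=2), 0.1 * np.eye(2),
                                       [1.0, 1.0]) for _ in range(6)]
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="mean-centered"):
            peb_fit(subj, X, param_subset=np.arange(2))

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        subj = [make_subject_posterior(rng.normal(size=2), 0.1 * np.eye(2),
                                       [1.0, 1.0]) for _ in range(6)]
        x = np.arange(6.0) - 2.5
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(ValueError):
            peb_fit(subj, X, param_subset=np.arange(2))

    def test_group_effect_recovered(self):
        """A known group shift on one parameter lands on the group column."""
        rng = np.random.default_rng(4)
        d, n = 3, 24
        group = np.repeat([0.0, 1.0], n // 2)
        subj = []
        for g in group:
            truth = np.array([0.2, -0.1, 0.0]) + g * np.array([0.3, 0.0, 0.0])
            m = truth + rng.normal(0, 0.05, d)
            subj.append(make_subject_posterior(m, 0.01 * np.eye(d),
                                               [1.0] * d))
        X = np.column_stack([np.ones(n), group - group.mean()])
        res = peb_fit(subj, X, param_subset=np.arange(d),
                      covariate_names=("common", "group"))
        eff = res.effect("group")
        assert eff[0] == pytest.approx(0.3, abs=0.08)
        assert abs(eff[1]) < 0.08 and abs(eff[2]) < 0.08


class TestBayesianModelReduction:
    def test_identical_priors_give_zero_change(self):
        rng = np.random.default_rng(5)
        S = np.diag([1.0, 2.0])
        post_m = rng.normal(size=2)
        post_c = 0.1 * np.eye(2)
        dF, rm, rc = bayesian_model_reduction(post_m, post_c, np.zeros(2), S,
                                              np.zeros(2), S.copy())
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rm, post_m)
        assert np.allclose(rc, post_c)

    def test_matches_direct_reduced_evidence(self):
        """Two-parameter linear-Gaussian toy, evidence ratio to 1e-8."""
        rng = np.random.default_rng(6)
        n, sigma = 30, 0.4
        X = rng.standard_normal((n, 2))
        y = X @ np.array([0.5, 0.0]) + sigma * rng.standard_normal(n)
        prec = 1 / sigma ** 2

        def posterior_and_evidence(prior_var):
            S0 = np.diag(prior_var)
            P0 = np.linalg.inv(S0)
            Sig = np.linalg.inv(prec * X.T @ X + P0)
            mu = Sig @ (prec * X.T @ y)
            logev = multivariate_normal.logpdf(
                y, mean=np.zeros(n), cov=sigma ** 2 * np.eye(n) + X @ S0 @ X.T)
            return mu, Sig, logev

        full_var = [1.0, 1.0]
        red_var = [1.0, 1e-8]
        mu_f, S_f, ev_f = posterior_and_evidence(full_var)
        mu_r, S_r, ev_r = posterior_and_evidence(red_var)
        dF, rm, rc = bayesian_model_reduction(
            mu_f, S_f, np.zeros(2), np.diag(full_var),
            np.zeros(2), np.diag(red_var))
        assert dF == pytest.approx(ev_r - ev_f, abs=1e-8)
        assert np.abs(rm - mu_r).max() < 1e-6
        assert np.abs(rc - S_r).max() < 1e-6

    def test_removing_null_parameter_helps_on_average(self):
        """Shrinking a truly-zero parameter raises the evidence on average."""
        rng = np.random.default_rng(7)
        gains = []
        for _ in range(20):
            n, sigma = 40, 0.5
            X = rng.standard_normal((n, 2))
            y = X @ np.array([0.8, 0.0]) + sigma * rng.standard_normal(n)
            prec = 1 / sigma ** 2
            S0 = np.eye(2)
            P0 = np.linalg.inv(S0)
            Sig = np.linalg.inv(prec * X.T @ X + P0)
            mu = Sig @ (prec * X.T @ y)
            dF, _, _ = bayesian_model_reduction(
                mu, Sig, np.zeros(2), S0, np.zeros(2),
                np.diag([1.0, 1e-8]))
            gains.append(dF)
        assert np.mean(gains) > 0


class TestGreedySearchAndBma:
    def _peb_from_effects(self, effects, se=0.05, n=40, seed=0):
        """PEB over one-parameter subjects with given per-column effects."""
        rng = np.random.default_rng(seed)
        group = np.repeat([0.0, 1.0], n // 2)
        Xc = group - group.mean()
        subj = []
        for g in group:
            val = effects[0] + (g - 0.5) * effects[1] + rng.normal(0, se)
            subj.append(make_subject_posterior([val], [[se ** 2]], [1.0]))
        X = np.column_stack([np.ones(n), Xc])
        return peb_fit(subj, X, param_subset=np.arange(1),
                       covariate_names=("common", "group"))

    def test_strong_effects_survive_with_high_pp(self):
        peb = self._peb_from_effects([0.5, 0.4], se=0.03)
        out = greedy_prune_and_average(peb)
        assert np.all(out.pp > 0.95)
        assert out.bma_mean[0] == pytest.approx(0.5, abs=0.1)

    def test_retained_models_bounded_and_normalised(self):
        peb = self._peb_from_effects([0.4, 0.0], se=0.05)
        out = greedy_prune_and_average(peb)
        assert len(out.searched_models) <= 256
        assert sum(w for _, _, w in out.searched_models) == pytest.approx(1.0)

    def test_null_group_effects_get_pruned(self):
        """Zero-effect group columns fall below presence threshold."""
        pruned = 0
        for rep in range(20):
            peb = self._peb_from_effects([0.4, 0.0], se=0.05, seed=rep)
            out = greedy_prune_and_average(peb)
            if out.effect_pp("group")[0] < 0.95:
                pruned += 1
        assert pruned >= 16


class TestDesignMatrix:
    def test_columns_centered_and_named(self):
        import pandas as pd
        table = pd.DataFrame({
            "group": ["control"] * 3 + ["MDD"] * 3,
            "SSRI": [False] * 3 + [True, False, True],
            "sex": ["male", "female"] * 3,
            "age": [15.0, 16.0, 17.0, 14.0, 16.5, 18.0],
            "handedness": ["right", "left", "right", "right", "right", "left"],
        })
        X, names = build_design_matrix(table)
        assert names[0] == "common"
        assert np.allclose(X[:, 0], 1.0)
        assert np.abs(X[:, 1:].mean(axis=0)).max() < 1e-12
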