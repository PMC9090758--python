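"""DE-MCMC machinery: moves, fixed-effects fits, group comparison, PPC."""

import numpy as np
import pandas as pd
import pytest

from affectpipe import lba
from affectpipe.hierarchical import (GroupDifference, SamplerConfig,
                                     compare_groups, crossover_step,
                                     de_proposal, fixed_effects_init,
                                     migration_step,
                                     posterior_predictive_cohort,
                                     subsample_cohort)


class TestDeMoves:
    def test_proposal_formula(self):
        assert de_proposal(1.0, 2.0, 0.5, 0.5) == pytest.approx(1.75)

    def test_zero_gamma_zero_jitter_is_identity(self):
        rng = np.random.default_rng(0)
        states = rng.standard_normal((8, 3))
        out, _ = crossover_step(states, lambda x, i: np.zeros(len(x)),
                                gamma=0.0, jitter_width=0.0, rng=1)
        assert np.array_equal(out, states)

    def test_fewer_than_four_chains_rejected(self):
        with pytest.raises(ValueError):
            crossover_step(np.zeros((3, 2)), lambda x, i: np.zeros(len(x)))

    def test_migration_prob_zero_is_identity(self):
        rng = np.random.default_rng(1)
        states = rng.standard_normal((6, 2))
        out, _ = migration_step(states, lambda x, i: np.zeros(len(x)), 0.0,
                                np.random.default_rng(2))
        assert np.array_equal(out, states)

    def test_gaussian_target_moments(self):
        """Crossover + burn-in migration reproduce a correlated Gaussian."""
        S = np.array([[1.0, 0.6], [0.6, 2.0]])
        P = np.linalg.inv(S)
        mu = np.array([1.0, -2.0])

        def lp(x, idx):
            d = x - mu
            return -0.5 * np.einsum("ij,jk,ik->i", d, P, d)

        rng = np.random.default_rng(3)
        states = rng.standard_normal((12, 2))
        draws = []
        lpv = None
        for it in range(6000):
            states, lpv = migration_step(
                states, lp, 0.05 if it < 1000 else 0.0, rng, lpv)
            states, lpv = crossover_step(states, lp, rng=rng, current_lp=lpv)
            if it >= 1000:
                draws.append(states.copy())
        X = np.array(draws).reshape(-1, 2)
        n_eff = 3000  # conservative effective sample size for MC error
        assert np.abs(X.mean(0) - mu).max() < 3 * np.sqrt(2 / n_eff)
        assert np.abs(np.cov(X.T) - S).max() < 0.15


class TestFixedEffectsInit:
    def test_recovers_drifts_at_large_n(self):
        p = lba.LBAParams(A=0.5, B=0.7, t0=0.3,
                          v_true=[2.2, 2.0, 1.4, 2.4],
                          v_false=[0.8, 0.8, 0.8, 0.8], sv_true=0.4)
        design = pd.DataFrame({"condition": np.repeat(lba.CONDITIONS, 125),
                               "onset": np.arange(500.0)})
        trials = lba.simulate_trials(p, design, rng_seed=42)
        trials["subject_id"] = "s1"
        est = fixed_effects_init(trials, "M_v")[0]
        names = lba.model_variant("M_v").param_names
        truth = lba.vector_from_params(p, lba.model_variant("M_v"))
        for n, e, t in zip(names, est, truth):
            if n.startswith("v_true"):
                assert abs(e - t) / t < 0.15, n

    def test_invariant_to_trial_order(self, small_cohort):
        trials = small_cohort.trials
        one = trials[trials["subject_id"] == "sub-001"].copy()
        est1 = fixed_effects_init(one, "M_null")
        est2 = fixed_effects_init(one.sample(frac=1.0, random_state=0),
                                  "M_null")
        assert np.allclose(est1, est2)

    def test_output_shape(self, small_cohort):
        trials = small_cohort.trials
        ctrl = trials[trials["group"] == "control"]
        est = fixed_effects_init(ctrl, "M_v")
        assert est.shape == (6, 12)


def make_posterior_like(draws_by_param, variant_name="M_v"):
    """Minimal PosteriorSamples stand-in built from explicit mu draws."""
    from affectpipe.hierarchical import PosteriorSamples
    variant = lba.model_variant(variant_name)
    p = variant.n_params
    n = len(next(iter(draws_by_param.values())))
    G = np.zeros((1, n, 2 * p))
    for name, draws in draws_by_param.items():
        G[0, :, variant.param_names.index(name)] = draws
    return PosteriorSamples(variant=variant, subject_ids=("s1",),
                            subject_draws=np.zeros((1, n, 1, p)),
                            group_draws=G,
                            pointwise_loglik=np.zeros((n, 1)),
                            burnin=0, thin=1)


class TestCompareGroups:
    def test_identical_posteriors_not_significant(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1.4, 0.1, 400)
        a = make_posterior_like({"v_true.neutral": d})
        b = make_posterior_like({"v_true.neutral": d.copy()})
        res = compare_groups(a, b, "v_true.neutral")
        assert res.interval[0] <= 0 <= res.interval[1]
        assert not res.significant

    def test_constructed_shift_detected(self):
        rng = np.random.default_rng(1)
        d = rng.normal(1.5, 0.02, 400)
        a = make_posterior_like({"v_true.neutral": d + 0.3})
        b = make_posterior_like({"v_true.neutral": d})
        res = compare_groups(a, b, "v_true.neutral")
        assert res.significant
        assert res.mean == pytest.approx(0.3, abs=0.01)
        assert res.interval[0] <= 0.3 + 1e-12
        assert res.interval[1] >= 0.3 - 1e-12

    def test_sign_convention_controls_minus_patients(self):
        d = np.linspace(1.0, 1.1, 100)
        a = make_posterior_like({"v_true.neutral": d + 1.0})
        b = make_posterior_like({"v_true.neutral": d})
        res = compare_groups(a, b, "v_true.neutral")
        assert np.all(res.delta_draws > 0)

    def test_missing_parameter_raises(self):
        a = make_posterior_like({"v_true.neutral": np.ones(10)})
        with pytest.raises(KeyError):
            compare_groups(a, a, "not_a_parameter")


class TestPosteriorPredictive:
    @pytest.fixture(scope="class")
    def fits(self):
        rng = np.random.default_rng(2)
        n = 50
        base = {
            "v_true.positive": rng.normal(2.2, 0.05, n),
            "v_true.negative": rng.normal(2.0, 0.05, n),
            "v_true.neutral": rng.normal(1.4, 0.05, n),
            "v_true.shapes": rng.normal(2.4, 0.05, n),
            "v_false.positive": rng.normal(0.8, 0.05, n),
            "v_false.negative": rng.normal(0.8, 0.05, n),
            "v_false.neutral": rng.normal(0.8, 0.05, n),
            "v_false.shapes": rng.normal(0.8, 0.05, n),
            "A": np.log(np.abs(rng.normal(0.5, 0.02, n))),
            "B": np.log(np.abs(rng.normal(0.7, 0.02, n))),
            "t0": np.log(np.abs(rng.normal(0.3, 0.01, n))),
            "sv_true": np.log(np.abs(rng.normal(0.4, 0.02, n))),
        }
        ctrl = make_posterior_like(base)
        pat = make_posterior_like({**base, "v_true.neutral":
                                   base["v_true.neutral"] - 0.14})
        # sigma slots stay 0 -> exp(0)=1; tighten them for the PPC
        for post in (ctrl, pat):
            post.group_draws[:, :, 12:] = np.log(0.1)
        return {"control": ctrl, "MDD": pat}

    def test_default_cohort_size(self, fits):
        sim = posterior_predictive_cohort(fits, n_per_group=25,
                                          trials_per_condition=5, seed=0)
        assert sim["subject_id"].nunique() == 50
        per = sim.groupby("subject_id").size()
        assert set(per) == {20}

    def test_subsample_sizes(self, fits):
        sim = posterior_predictive_cohort(fits, n_per_group=40,
                                          trials_per_condition=5, seed=1)
        sub = subsample_cohort(sim, n_controls=33, n_patients=30, seed=2)
        counts = sub.groupby("group")["subject_id"].nunique()
        assert counts["control"] == 33
        assert counts["MDD"] == 30

    def test_rt_pattern_follows_generating_drifts(self, fits):
        sim = posterior_predictive_cohort(fits, n_per_group=60,
                                          trials_per_condition=10, seed=3)
        ctrl = sim[sim["group"] == "control"]
        means = ctrl.groupby("condition")["rt"].mean()
        assert means["positive"] < means["neutral"]
        assert means["negative"] < means["neutral"]
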