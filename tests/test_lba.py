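"""LBA closed forms against Monte-Carlo and numerical oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from affectpipe import lba


def mc_first_passage(A, b, v, sv, n=10 ** 6, seed=0):
    """First-passage sample under start ~ U(0,A), drift ~ TruncNormal(>0)."""
    rng = np.random.default_rng(seed)
    k = rng.uniform(0, A, n) if A > 0 else np.zeros(n)
    d = truncnorm.rvs(-v / sv, np.inf, loc=v, scale=sv, size=n,
                      random_state=rng)
    return (b - k) / d


class TestAccumulatorCdf:
    def test_zero_time_has_zero_mass(self):
        assert lba.accumulator_cdf(0.0, 0.5, 1.0, 1.0, 1.0) == 0.0

    def test_limit_is_one_under_positive_truncation(self):
        # the truncated race is heavy-tailed (P(T > t) ~ c/t), so the
        # limit is approached slowly; evaluate far out with a modest
        # tolerance
        assert lba.accumulator_cdf(1e4, 0.5, 1.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_matches_million_draw_monte_carlo(self):
        T = mc_first_passage(0.5, 1.0, 1.0, 1.0)
        est = np.mean(T <= 1.0)
        se = np.sqrt(est * (1 - est) / T.size)
        closed = lba.accumulator_cdf(1.0, 0.5, 1.0, 1.0, 1.0)
        assert abs(closed - est) < 3 * se

    def test_nondecreasing_and_bounded(self):
        t = np.linspace(0, 10, 400)
        F = lba.accumulator_cdf(t, 0.5, 1.0, 1.0, 1.0)
        assert np.all(np.diff(F) >= -1e-12)
        assert F.min() >= 0 and F.max() <= 1

    @pytest.mark.parametrize("bad", [
        dict(A=-0.1, b=1.0, v=1.0, sv=1.0),
        dict(A=0.5, b=0.4, v=1.0, sv=1.0),
        dict(A=0.5, b=1.0, v=1.0, sv=0.0),
    ])
    def test_domain_errors_name_the_field(self, bad):
        with pytest.raises(ValueError):
            lba.accumulator_cdf(1.0, **bad)


class TestAccumulatorPdf:
    def test_zero_outside_support(self):
        assert lba.accumulator_pdf(-1.0, 0.5, 1.0, 1.0, 1.0) == 0.0
        assert lba.accumulator_pdf(0.0, 0.5, 1.0, 1.0, 1.0) == 0.0

    def test_equals_cdf_derivative(self):
        h = 1e-5
        for t in (0.4, 1.0, 2.5):
            num = (lba.accumulator_cdf(t + h, 0.5, 1.0, 1.0, 1.0)
                   - lba.accumulator_cdf(t - h, 0.5, 1.0, 1.0, 1.0)) / (2 * h)
            assert lba.accumulator_pdf(t, 0.5, 1.0, 1.0, 1.0) == pytest.approx(num, abs=1e-6)

    def test_integrates_to_one(self):
        # the truncated-drift first-passage time is heavy tailed (drifts
        # near zero), so the integral needs an adaptive rule to infinity
        from scipy.integrate import quad
        total, _ = quad(lambda t: lba.accumulator_pdf(t, 0.5, 1.0, 1.0, 1.0),
                        0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-4)


class TestTrialLoglik:
    def test_rt_before_nondecision_time_is_floored(self, base_params):
        ll = lba.trial_loglik("correct", base_params.t0 - 0.01, "neutral",
                              base_params)
        assert ll == lba.LOGLIK_FLOOR

    def test_identical_accumulators_split_probability_equally(self):
        p = lba.LBAParams(A=0.5, B=0.5, t0=0.3, v_true=1.0, v_false=1.0,
                          sv_true=1.0)
        assert lba.defective_prob_correct(p, "neutral") == pytest.approx(0.5, abs=1e-3)

    def test_matches_simulation_density(self, base_params, mv):
        """Defective density at rt=1.2 vs a KDE of 10^6 simulated trials."""
        design = pd.DataFrame({"condition": ["neutral"] * (10 ** 6),
                               "onset": np.zeros(10 ** 6)})
        trials = lba.simulate_trials(base_params, design, rng_seed=7,
                                     response_window=np.inf)
        rts = trials.loc[trials["correct"], "rt"].to_numpy()
        from scipy.stats import gaussian_kde
        kde = gaussian_kde(rts, bw_method=0.03)
        dens = kde(1.2)[0] * (len(rts) / len(trials))
        ll = lba.trial_loglik("correct", 1.2, "neutral", base_params)
        assert ll == pytest.approx(np.log(dens), abs=0.02)

    def test_defective_densities_sum_to_one(self, base_params):
        p_corr = lba.defective_prob_correct(base_params, "neutral")
        flip = lba.LBAParams(A=0.5, B=0.5, t0=0.3, v_true=0.6, v_false=1.2,
                             sv_true=1.0)
        p_err = 1.0 - lba.defective_prob_correct(flip, "neutral")
        # p_err of original = P(mismatching accumulator wins)
        t = np.linspace(1e-6, 60, 20000)
        f = lba._acc_pdf_raw(t, 0.5, 1.0, 0.6, 1.0)
        S = 1 - lba._acc_cdf_raw(t, 0.5, 1.0, 1.2, 1.0)
        p_err = np.trapezoid(f * S, t)
        assert p_corr + p_err == pytest.approx(1.0, abs=1e-3)


class TestSimulateTrials:
    def test_full_session_has_80_trials(self, small_cohort):
        for rec in small_cohort.subjects.values():
            assert len(rec.trials) == 80
            counts = rec.trials["condition"].value_counts()
            assert set(counts) == {20}

    def test_deterministic_race_with_degenerate_params(self, flat_design):
        # sv_true -> 0 with A = 0 makes the matching accumulator
        # deterministic; a strongly negative error drift (truncated to
        # positive with unit SD) never finishes first
        p = lba.LBAParams(A=0.0, B=1.0, t0=0.3, v_true=2.0, v_false=-5.0,
                          sv_true=1e-9)
        trials = lba.simulate_trials(p, flat_design, rng_seed=0)
        assert np.allclose(trials["rt"], 0.8, atol=1e-6)
        assert trials["correct"].all()

    def test_choice_proportions_match_defective_integral(self, base_params):
        design = pd.DataFrame({"condition": ["neutral"] * (10 ** 5),
                               "onset": np.zeros(10 ** 5)})
        trials = lba.simulate_trials(base_params, design, rng_seed=3,
                                     response_window=np.inf)
        emp = trials["correct"].mean()
        theo = lba.defective_prob_correct(base_params, "neutral")
        se = np.sqrt(theo * (1 - theo) / len(trials))
        assert abs(emp - theo) < 3 * se

    def test_same_seed_reproduces(self, base_params, flat_design):
        a = lba.simulate_trials(base_params, flat_design, rng_seed=5)
        b = lba.simulate_trials(base_params, flat_design, rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_simulated_rts_match_implied_cdf(self, base_params):
        """KS distance between simulated RTs and the model-implied CDF."""
        design = pd.DataFrame({"condition": ["neutral"] * (10 ** 5),
                               "onset": np.zeros(10 ** 5)})
        trials = lba.simulate_trials(base_params, design, rng_seed=9,
                                     response_window=np.inf)
        rts = np.sort(trials["rt"].to_numpy())
        dt = rts - base_params.t0
        # P(T <= t) regardless of winner = 1 - survivor product
        S1 = 1 - lba._acc_cdf_raw(dt, 0.5, 1.0, 1.2, 1.0)
        S2 = 1 - lba._acc_cdf_raw(dt, 0.5, 1.0, 0.6, 1.0)
        F = 1 - S1 * S2
        emp = np.arange(1, len(rts) + 1) / len(rts)
        assert np.abs(F - emp).max() < 0.01


class TestModelVariants:
    @pytest.mark.parametrize("name,n_params", [("M_v", 12), ("M_B", 9),
                                               ("M_null", 6)])
    def test_parameter_counts(self, name, n_params):
        v = lba.model_variant(name)
        assert v.n_params == n_params

    def test_chain_rule_gives_36_chains_for_winning_model(self):
        assert 3 * lba.model_variant("M_v").n_params == 36

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            lba.model_variant("M_x")

    def test_vector_roundtrip(self, base_params, mv):
        vec = lba.vector_from_params(base_params, mv)
        back = lba.params_from_vector(vec, mv)
        assert np.allclose(back.v_true, base_params.v_true)
        assert back.A == base_params.A

    def test_sampling_scale_roundtrip(self, mv):
        rng = np.random.default_rng(0)
        theta = np.abs(rng.standard_normal((5, 12))) + 0.1
        psi = lba.to_sampling_scale(theta, mv)
        assert np.allclose(lba.from_sampling_scale(psi, mv), theta)


class TestMonotonicity:
    def test_correct_probability_increases_with_drift(self):
        """Raising the matching drift raises accuracy over a grid."""
        grid = np.linspace(0.8, 2.5, 8)
        probs = []
        for v in grid:
            p = lba.LBAParams(A=0.5, B=0.5, t0=0.3, v_true=v, v_false=0.6,
                              sv_true=1.0)
            probs.append(lba.defective_prob_correct(p, "neutral"))
        assert np.all(np.diff(probs) > 0)

    def test_sv_false_fixed_at_one(self):
        with pytest.raises(ValueError):
            lba.LBAParams(A=0.5, B=0.5, t0=0.3, v_true=1.0, v_false=0.5,
                          sv_true=1.0, sv_false=0.9)


class TestClosedFormProperties:
    """Property-based invariants of the accumulator distributions."""

    def test_cdf_monotone_and_bounded_over_random_parameters(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(st.floats(0.01, 1.5), st.floats(0.05, 2.0),
               st.floats(-1.0, 3.0), st.floats(0.2, 2.0))
        def check(A, B, v, sv):
            t = np.linspace(1e-6, 20, 300)
            F = lba.accumulator_cdf(t, A, A + B, v, sv)
            assert np.all(np.diff(F) >= -1e-9)
            assert F.min() >= 0.0 and F.max() <= 1.0
            f = lba.accumulator_pdf(t, A, A + B, v, sv)
            assert np.all(f >= 0.0)

        check()
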