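import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wmcpm import stats as st
from wmcpm import synth


class TestShapiroWilk:
    def test_normal_quantiles_pass(self):
        x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        res = st.shapiro_wilk(x)
        assert res.p > 0.5 and 0 < res.W <= 1

    def test_skewed_sample_fails(self):
        x = sps.expon.ppf((np.arange(1, 101) - 0.5) / 100)
        assert st.shapiro_wilk(x).p < 0.01

    def test_too_small_or_constant_rejected(self):
        with pytest.raises(ValueError):
            st.shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            st.shapiro_wilk(np.ones(10))


def rank_then_pearson(x, y):
    """Brute-force oracle: mid-rank both vectors, Pearson on the ranks."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return (rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc))


class TestSpearman:
    def test_monotone_transforms(self, rng):
        x = rng.normal(size=30)
        assert st.spearman_ci(x, np.exp(x)).rho == pytest.approx(1.0)
        assert st.spearman_ci(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self):
        x = np.array([1, 2, 2, 3, 5, 5, 5, 8, 9, 9], dtype=float)
        y = np.array([3, 1, 4, 4, 6, 2, 7, 7, 9, 5], dtype=float)
        res = st.spearman_ci(x, y)
        assert res.rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)
        # p agrees with the t approximation
        t = res.rho * np.sqrt((10 - 2) / (1 - res.rho**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-12)

    def test_ci_is_bonett_wright(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = st.spearman_ci(x, y)
        se = np.sqrt((1 + res.rho**2 / 2) / 47)
        lo = np.tanh(np.arctanh(res.rho) - 1.959963984540054 * se)
        assert res.ci[0] == pytest.approx(lo, abs=1e-12)
        assert -1 <= res.ci[0] <= res.rho <= res.ci[1] <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            st.spearman_ci(np.ones(10), np.arange(10.0))


class TestModerationTable:
    def test_shape_and_coding(self):
        table = st.prepare_moderation_table([60.0, 70, 50], [50.0, 65, 40], [1.0, 2, 3])
        assert len(table) == 6
        assert table["moderator"].sum() == pytest.approx(0.0)
        assert table["intensity"].mean() == pytest.approx(0.5)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            st.prepare_moderation_table([1.0], [1.0, 2.0], [0.0])


def ols_difference_oracle(table):
    """Difference-score OLS oracle for the interaction line."""
    wide = table.pivot(index="subject", columns="intensity", values="outcome")
    mod = table.groupby("subject")["moderator"].first()
    d = (wide[1] - wide[0]).loc[mod.index].to_numpy()
    x = mod.to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ d)
    resid = d - X @ beta
    sigma2 = resid @ resid / (len(d) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return {"intensity": (beta[0], se[0]), "interaction": (beta[1], se[1])}


class TestModerationFit:
    def test_interaction_equals_difference_score_ols(self):
        table = synth.gen_moderation_cohort(n_subjects=60, interaction=80.0, seed=2)
        fit = st.fit_moderation(table)
        oracle = ols_difference_oracle(table)
        for term in ("intensity", "interaction"):
            est, se = oracle[term]
            assert fit.terms[term].estimate == pytest.approx(est, abs=1e-8)
            assert fit.terms[term].se == pytest.approx(se, abs=1e-8)
            assert fit.terms[term].t == pytest.approx(est / se, abs=1e-8)

    def test_intensity_estimate_is_mean_condition_difference(self):
        table = synth.gen_moderation_cohort(n_subjects=40, seed=5)
        fit = st.fit_moderation(table)
        wide = table.pivot(index="subject", columns="intensity", values="outcome")
        assert fit.terms["intensity"].estimate == pytest.approx(
            (wide[1] - wide[0]).mean(), abs=1e-10
        )

    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: iterative REML via statsmodels agrees with
        the closed-form fit on estimates, SEs, and variance components."""
        import statsmodels.formula.api as smf

        table = synth.gen_moderation_cohort(n_subjects=50, interaction=40.0, seed=9)
        fit = st.fit_moderation(table)
        sm_fit = smf.mixedlm(
            "outcome ~ intensity * moderator", table, groups=table["subject"]
        ).fit(reml=True)
        mapping = {
            "intercept": "Intercept",
            "intensity": "intensity",
            "moderator": "moderator",
            "interaction": "intensity:moderator",
        }
        for ours, theirs in mapping.items():
            assert fit.terms[ours].estimate == pytest.approx(
                sm_fit.params[theirs], abs=1e-6
            )
            # statsmodels stops at its own iterative convergence tolerance
            assert fit.terms[ours].se == pytest.approx(sm_fit.bse[theirs], rel=1e-4)
        assert fit.residual_var == pytest.approx(float(sm_fit.scale), rel=1e-4)
        assert fit.random_intercept_var == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )

    def test_fixed_effects_invariant_to_reml_vs_ml(self):
        import statsmodels.formula.api as smf

        table = synth.gen_moderation_cohort(n_subjects=30, seed=13)
        fit = st.fit_moderation(table)
        ml_fit = smf.mixedlm(
            "outcome ~ intensity * moderator", table, groups=table["subject"]
        ).fit(reml=False)
        assert fit.terms["interaction"].estimate == pytest.approx(
            ml_fit.params["intensity:moderator"], abs=1e-6
        )

    def test_df_is_between_within(self):
        table = synth.gen_moderation_cohort(n_subjects=104, seed=1)
        fit = st.fit_moderation(table)
        assert all(t.df == 102 for t in fit.terms.values())

    def test_unbalanced_rejected(self):
        table = synth.gen_moderation_cohort(n_subjects=10, seed=0).iloc[:-1]
        with pytest.raises(ValueError, match="listwise"):
            st.fit_moderation(table)

    def test_zero_interaction_ci_coverage(self):
        """CI for a null interaction covers 0 at close to nominal rate."""
        covered = 0
        for seed in range(100):
            table = synth.gen_moderation_cohort(n_subjects=50, interaction=0.0, seed=seed)
            ci = st.fit_moderation(table).terms["interaction"].ci
            covered += ci[0] <= 0.0 <= ci[1]
        assert covered >= 93


class TestSimpleSlopes:
    def test_zero_interaction_slopes_equal_main_effect(self):
        table = synth.gen_moderation_cohort(n_subjects=300, seed=3)
        fit = st.fit_moderation(table)
        # force an exactly-zero interaction to isolate the identity
        fit.terms["interaction"].estimate = 0.0
        slopes = st.simple_slopes(fit)
        for s in slopes:
            assert s.estimate == pytest.approx(fit.terms["intensity"].estimate)

    def test_slopes_differ_by_two_sd_interactions(self):
        table = synth.gen_moderation_cohort(n_subjects=80, interaction=120.0, seed=6)
        fit = st.fit_moderation(table)
        lo, hi = st.simple_slopes(fit)
        expected = 2 * fit.moderator_sd * fit.terms["interaction"].estimate
        assert hi.estimate - lo.estimate == pytest.approx(expected, abs=1e-10)

    def test_recovers_planted_interaction_pattern(self):
        planted = 200.0
        table = synth.gen_moderation_cohort(
            n_subjects=500, interaction=planted, moderator_sd=1.0, seed=7
        )
        fit = st.fit_moderation(table)
        assert abs(fit.terms["interaction"].estimate - planted) < 2 * fit.terms["interaction"].se

    def test_average_of_slopes_is_main_effect(self):
        table = synth.gen_moderation_cohort(n_subjects=60, interaction=75.0, seed=8)
        fit = st.fit_moderation(table)
        lo, hi = st.simple_slopes(fit)
        assert (lo.estimate + hi.estimate) / 2 == pytest.approx(
            fit.terms["intensity"].estimate, abs=1e-10
        )


class TestPower:
    def test_published_sample_size(self):
        assert st.power_n_for_r(0.37, alpha=0.05, power=0.80).answer == 55

    def test_self_consistency_at_boundary(self):
        n = int(st.power_n_for_r(0.37).answer)
        assert st.correlation_power(n, 0.37) >= 0.80
        assert st.correlation_power(n - 1, 0.37) < 0.80

    def test_large_effect_needs_few_subjects(self):
        assert st.power_n_for_r(0.99).answer <= 6

    def test_min_detectable_r_published_value(self):
        assert round(st.min_detectable_r(104).answer, 2) == 0.27

    def test_min_detectable_r_monotone_in_n(self):
        rs = [st.min_detectable_r(n).answer for n in (30, 100, 300, 1000, 10000)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.03

    def test_r_solver_round_trips(self):
        for n in (50, 104, 250):
            r = st.min_detectable_r(n).answer
            assert st.correlation_power(n, r) == pytest.approx(0.80, abs=1e-6)
            assert st.power_n_for_r(r).answer <= n

    def test_min_detectable_f_published_value(self):
        assert round(st.min_detectable_f(104, n_predictors=3, test_df=1).answer, 2) == 0.28

    def test_f_solver_round_trips(self):
        f = st.min_detectable_f(104, 3, 1).answer
        assert st.regression_f_power(f, 104, 3, 1) == pytest.approx(0.80, abs=1e-8)

    def test_power_at_alpha_gives_null_f(self):
        f = st.min_detectable_f(104, 3, 1, alpha=0.05, power=0.0501).answer
        assert f < 0.05
        with pytest.raises(ValueError):
            st.min_detectable_f(104, 3, 1, power=0.04)


class TestCorrelationBattery:
    def test_planted_coupling_detected_and_fd_null(self, rng):
        n = 150
        strength = rng.normal(0.09, 0.04, size=n)
        behavior = 0.7 + 0.9 * strength + rng.normal(0, 0.05, size=n)
        fd = rng.normal(0.07, 0.02, size=n)
        table = pd.DataFrame({"combined": strength, "acc_2back": behavior, "mean_fd": fd})
        out = st.correlation_battery(
            table, [("combined", "acc_2back"), ("mean_fd", "acc_2back")]
        )
        coupled = out[(out.x == "combined")].iloc[0]
        null = out[(out.x == "mean_fd")].iloc[0]
        assert coupled.p < 0.001 and coupled.rho > 0.3
        assert null.p > 0.05

    def test_n_honors_missingness(self, rng):
        table = pd.DataFrame(
            {"a": rng.normal(size=20), "b": np.r_[rng.normal(size=14), [np.nan] * 6]}
        )
        out = st.correlation_battery(table, [("a", "b")])
        assert out.iloc[0]["n"] == 14
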