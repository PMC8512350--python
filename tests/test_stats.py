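"""Paired tests, ROC, three-level mixed models, ICC/R-squared decompositions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from perclos.stats import (
    DegenerateDataError,
    ModelFit,
    StatsError,
    SubjectiveFatigueModel,
    compare_models,
    delta_r2,
    fit_three_level,
    icc,
    paired_test,
    r2_nakagawa,
    roc_analysis,
)
from perclos.synthetic import FssSimConfig, generate_fss_dataset


class TestPairedTest:
    def test_identical_samples_give_zero_t_and_d(self):
        res = paired_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.t == 0.0 and res.d == 0.0 and res.p == 1.0

    def test_t_and_p_match_scipy_oracle(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(10, 2, 12)
        post = pre + rng.normal(1, 1.5, 12)
        res = paired_test(pre, post)
        t_ref, p_ref = sps.ttest_rel(post, pre)
        assert res.t == pytest.approx(float(t_ref), abs=1e-10)
        assert res.p == pytest.approx(float(p_ref), abs=1e-12)
        assert res.df == 11

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(2)
        pre, post = rng.normal(size=9), rng.normal(size=9)
        res = paired_test(pre, post)
        t_ref, _ = sps.ttest_1samp(post - pre, 0.0)
        assert res.t == pytest.approx(float(t_ref), abs=1e-10)

    def test_dunlap_d_reduces_to_mean_diff_over_common_sd(self):
        # equal pre/post SDs: the correlation-corrected d is mean diff / SD
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        post = pre[::-1] + 2.0  # same SD, shifted
        res = paired_test(pre, post)
        assert res.d == pytest.approx(2.0 / np.std(pre, ddof=1), rel=1e-9)

    def test_dz_variant(self):
        pre = np.array([1.0, 2.0, 4.0])
        post = np.array([2.0, 4.0, 5.0])
        res = paired_test(pre, post, method="dz")
        diff = post - pre
        assert res.d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_single_pair_raises(self):
        with pytest.raises(StatsError):
            paired_test([1.0], [2.0])

    def test_constant_nonzero_shift_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_test([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        res = roc_analysis(scores, labels, n_boot=50, seed=0)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 0.0 < res.optimal_threshold < 1.0

    def test_identical_scores_give_half(self):
        res = roc_analysis(np.ones(10), np.r_[np.zeros(5, bool), np.ones(5, bool)], n_boot=10)
        assert res.auc == 0.5

    def test_auc_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=16)
        labels = np.r_[np.zeros(8, bool), np.ones(8, bool)]
        pos, neg = scores[labels], scores[~labels]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        res = roc_analysis(scores, labels, n_boot=10)
        assert res.auc == pytest.approx(wins / 64.0, abs=1e-12)

    def test_matches_sklearn_oracle(self):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]  # both classes present
        res = roc_analysis(scores, labels, n_boot=10)
        assert res.auc == pytest.approx(float(roc_auc_score(labels, scores)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20)
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        a = roc_analysis(scores, labels, n_boot=10).auc
        b = roc_analysis(np.exp(3 * scores), labels, n_boot=10).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(0, 1, 15), rng.normal(1.2, 1, 15)]
        labels = np.r_[np.zeros(15, bool), np.ones(15, bool)]
        r1 = roc_analysis(scores, labels, n_boot=500, seed=42)
        r2 = roc_analysis(scores, labels, n_boot=500, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high

    def test_single_class_raises(self):
        with pytest.raises(StatsError):
            roc_analysis([1.0, 2.0], [True, True], n_boot=10)


def make_fit(vs, vc, vr, loglik=-100.0, n_params=4, fe=None, sf2=None, name="m", n_obs=32):
    return ModelFit(
        name=name,
        fixed_effects=fe if fe is not None else {"intercept": (1.0, 0.5)},
        var_subject=vs,
        var_condition=vc,
        var_residual=vr,
        loglik=loglik,
        aic=2 * n_params - 2 * loglik,
        n_params=n_params,
        converged=True,
        n_obs=n_obs,
        fixed_effect_variance=sf2,
    )


class TestIcc:
    def test_equal_subject_and_condition_shares(self):
        assert icc(make_fit(4.0, 4.0, 2.0)) == (pytest.approx(0.4), pytest.approx(0.4))

    def test_pure_residual_gives_zero_iccs(self):
        assert icc(make_fit(0.0, 0.0, 5.0)) == (0.0, 0.0)

    def test_level_labels_follow_components(self):
        icc2, icc3 = icc(make_fit(1.0, 2.0, 3.0))
        assert icc2 == pytest.approx(2 / 6)
        assert icc3 == pytest.approx(1 / 6)

    def test_iccs_sum_to_at_most_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0, 10, 3)
            icc2, icc3 = icc(make_fit(*v))
            assert 0.0 <= icc2 + icc3 <= 1.0

    def test_requires_intercept_only_fit(self):
        fit = make_fit(1.0, 1.0, 1.0, fe={"intercept": (0, 1), "time": (1, 1)})
        with pytest.raises(StatsError):
            icc(fit)

    def test_all_zero_variances_raise(self):
        with pytest.raises(DegenerateDataError):
            icc(make_fit(0.0, 0.0, 0.0))


class TestR2:
    def test_zero_fixed_variance_gives_zero_marginal(self):
        marginal, _ = r2_nakagawa(make_fit(1.0, 1.0, 1.0, sf2=0.0))
        assert marginal == 0.0

    def test_unit_components(self):
        marginal, conditional = r2_nakagawa(make_fit(1.0, 1.0, 1.0, sf2=1.0))
        assert marginal == pytest.approx(0.25)
        assert conditional == pytest.approx(0.75)

    def test_marginal_never_exceeds_conditional(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vs, vc, vr, sf2 = rng.uniform(0.01, 5, 4)
            marginal, conditional = r2_nakagawa(make_fit(vs, vc, vr, sf2=sf2))
            assert marginal <= conditional

    def test_zero_denominator_raises(self):
        with pytest.raises(DegenerateDataError):
            r2_nakagawa(make_fit(0.0, 0.0, 0.0, sf2=0.0))


class TestDeltaR2:
    def test_identical_fits_give_zero_everywhere(self):
        a = make_fit(2.0, 3.0, 4.0)
        assert delta_r2(a, a) == {"subject": 0.0, "condition": 0.0, "residual": 0.0}

    def test_proportional_reduction(self):
        ref, new = make_fit(100.0, 1.0, 1.0), make_fit(63.0, 1.0, 1.0)
        assert delta_r2(ref, new)["subject"] == pytest.approx(0.37)

    def test_variance_increase_reported_negative(self):
        ref, new = make_fit(1.0, 1.0, 10.0), make_fit(1.0, 1.0, 12.0)
        assert delta_r2(ref, new)["residual"] == pytest.approx(-0.2)

    def test_zero_reference_level_is_missing(self):
        ref, new = make_fit(0.0, 1.0, 1.0), make_fit(0.5, 1.0, 1.0)
        assert delta_r2(ref, new)["subject"] is None


class TestCompareModels:
    def test_chi2_from_reported_minus2ll_values(self):
        m1 = ModelFit.from_minus2ll("M1 intercepts", 289.46, 4)
        m2 = ModelFit.from_minus2ll("M2 time", 287.44, 5)
        table = compare_models([m1, m2]).table
        assert table.loc[1, "chi2"] == pytest.approx(2.02, abs=1e-9)

    def test_identical_loglik_gives_zero_chi2_p_one(self):
        m1 = ModelFit.from_minus2ll("a", 100.0, 4)
        m2 = ModelFit.from_minus2ll("b", 100.0, 5)
        table = compare_models([m1, m2]).table
        assert table.loc[1, "chi2"] == 0.0
        assert table.loc[1, "p"] == 1.0

    def test_chi2_5673_df1_is_significant_at_05_not_01(self):
        p = float(sps.chi2.sf(5.673, 1))
        m2 = ModelFit.from_minus2ll("ref", 287.44, 5)
        m4 = ModelFit.from_minus2ll("ecd", 287.44 - 5.673, 6)
        table = compare_models([m2, m4]).table
        assert table.loc[1, "p"] == pytest.approx(p, abs=1e-9)
        assert 0.01 < table.loc[1, "p"] < 0.05

    def test_default_references_follow_evaluation_ladder(self):
        fits = [ModelFit.from_minus2ll(f"m{i}", 300.0 - i, 4 + i) for i in range(5)]
        table = compare_models(fits).table
        assert list(table["vs"]) == ["", "m0", "m1", "m1", "m1"]

    def test_non_nested_or_mismatched_data_raise(self):
        a = make_fit(1, 1, 1, n_params=5, n_obs=32)
        b = make_fit(1, 1, 1, n_params=4, n_obs=32)
        with pytest.raises(StatsError):
            compare_models([a, b])
        c = make_fit(1, 1, 1, n_params=6, n_obs=30)
        with pytest.raises(StatsError):
            compare_models([a, c])


@pytest.fixture(scope="module")
def big_table():
    config = FssSimConfig(
        n_subjects=200, var_subject=100.0, var_condition=100.0, var_residual=100.0,
        fixed_time_slope=5.0, fixed_indicator_slope=10.0,
        indicator_condition_shift=0.0, seed=17,
    )
    return config, generate_fss_dataset(config)


class TestThreeLevelModel:
    def test_variance_components_recovered(self):
        # replicate-averaged: single-fit subject-level estimates at n=200
        # carry ~25% sampling SD, so unbiasedness is the testable property
        estimates = []
        for seed in range(8):
            config = FssSimConfig(
                n_subjects=200, var_subject=100.0, var_condition=100.0,
                var_residual=100.0, fixed_time_slope=5.0,
                fixed_indicator_slope=10.0, indicator_condition_shift=0.0,
                seed=400 + seed,
            )
            fit = fit_three_level(generate_fss_dataset(config), ("time", "indicator"))
            assert fit.converged
            estimates.append([fit.var_subject, fit.var_condition, fit.var_residual])
        means = np.mean(estimates, axis=0)
        assert means == pytest.approx([100.0, 100.0, 100.0], rel=0.2)

    def test_fixed_effects_recovered(self, big_table):
        config, df = big_table
        fit = fit_three_level(df, ("time", "indicator"))
        sd = df["indicator"].std(ddof=0)
        assert fit.fixed_effects["time"][0] == pytest.approx(5.0, abs=2.0)
        assert fit.fixed_effects["indicator"][0] == pytest.approx(10.0 * sd, rel=0.1)

    def test_zero_variance_levels_estimate_near_boundary(self):
        config = FssSimConfig(
            n_subjects=100, var_subject=0.0, var_condition=0.0, var_residual=100.0,
            fixed_time_slope=0.0, fixed_indicator_slope=0.0, seed=23,
        )
        fit = fit_three_level(generate_fss_dataset(config), ())
        assert 0.0 <= fit.var_subject <= 0.05 * fit.var_residual
        assert 0.0 <= fit.var_condition <= 0.05 * fit.var_residual

    def test_refit_is_deterministic(self, big_table):
        _, df = big_table
        f1 = fit_three_level(df, ("time",))
        f2 = fit_three_level(df, ("time",))
        assert f1 == f2

    def test_aic_identity_and_param_count(self, big_table):
        _, df = big_table
        fit = fit_three_level(df, ("time", "indicator"))
        assert fit.n_params == 6
        assert fit.aic == pytest.approx(2 * 6 - 2 * fit.loglik)

    def test_missing_columns_listed(self):
        with pytest.raises(StatsError, match="fss_s"):
            SubjectiveFatigueModel(pd.DataFrame({"subject": [0, 1], "condition": "r", "occasion": 0}))

    def test_constant_response_is_degenerate(self):
        df = generate_fss_dataset(FssSimConfig(n_subjects=5))
        df["fss_s"] = 1.0
        with pytest.raises(DegenerateDataError):
            SubjectiveFatigueModel(df)

    def test_summary_mentions_all_levels(self, big_table):
        _, df = big_table
        text = fit_three_level(df, ("time",)).summary()
        assert "subjects" in text and "condition" in text and "residual" in text

    def test_model_results_round_trip_through_decompositions(self, big_table):
        _, df = big_table
        m0 = fit_three_level(df, ())
        m1 = fit_three_level(df, ("time",))
        m2 = fit_three_level(df, ("time", "indicator"))
        icc2, icc3 = icc(m0)
        assert 0 < icc2 < 1 and 0 < icc3 < 1
        marginal, conditional = r2_nakagawa(m2)
        assert marginal <= conditional
        dr2 = delta_r2(m1, m2)
        assert set(dr2) == {"subject", "condition", "residual"}
        table = compare_models([m0, m1, m2]).table
        assert (table.loc[1:, "chi2"] >= -1e-6).all()
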