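"""Heteroscedastic one-way model, Tukey comparisons, Welch t and
trait-effect regressions."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beflitter import (
    DataError,
    HeteroscedasticOneWay,
    TraitEffectRegression,
    ValidationError,
    diversity_loss_anova,
    fit_hetero_oneway,
    regress_effect_on_trait,
    tukey_pairwise,
    welch_t,
)
from beflitter.inference import compact_letter_display

# Frozen oracle: nlme::gls(y ~ group, weights = varIdent(form = ~1|group),
# method = "REML") on the dataset generated below (three normal groups,
# numpy PCG64 seed 7).  anova() F/p, logLik and per-group variances.
GLS_ORACLE = {
    "F": 10.8318065112,
    "p": 0.001227213122,
    "loglik": -19.3758914050,
    "variances": {"g1": 0.2040262415, "g2": 6.5568906304, "g3": 0.1307232527},
    "equal_var_F": 9.1343117544,
    "equal_var_p": 0.002543449978,
}


def _oracle_data():
    rng = np.random.default_rng(7)
    groups, values = [], []
    for g, (mu, sd, n) in {
        "g1": (10.0, 1.0, 5),
        "g2": (12.5, 3.0, 6),
        "g3": (9.0, 0.5, 7),
    }.items():
        vals = mu + sd * rng.standard_normal(n)
        groups += [g] * n
        values += list(vals)
    return np.array(values), np.array(groups)


class TestHeteroOneway:
    def test_textbook_anova_f_150(self):
        y = [0, 1, 2, 10, 11, 12]
        g = ["a"] * 3 + ["b"] * 3
        fit = fit_hetero_oneway(y, g, equal_var=True)
        assert fit.f == pytest.approx(150.0, rel=1e-12)
        assert (fit.df_num, fit.df_den) == (1, 4)

    def test_two_group_heteroscedastic_f_equals_welch_t_squared(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.0, 3.0, 13)
        fit = fit_hetero_oneway(
            np.concatenate([a, b]), ["a"] * 8 + ["b"] * 13, equal_var=False
        )
        t_welch = stats.ttest_ind(a, b, equal_var=False).statistic
        assert fit.f == pytest.approx(t_welch**2, rel=1e-6)

    def test_identical_data_gives_zero_f(self):
        fit = fit_hetero_oneway([5.0] * 9, ["a", "b", "c"] * 3)
        assert fit.f == 0.0

    def test_matches_frozen_gls_varident_oracle(self):
        y, g = _oracle_data()
        fit = fit_hetero_oneway(y, g)
        assert fit.f == pytest.approx(GLS_ORACLE["F"], rel=1e-6)
        assert fit.p == pytest.approx(GLS_ORACLE["p"], rel=1e-4)
        assert fit.loglik_reml == pytest.approx(GLS_ORACLE["loglik"], rel=1e-7)
        for grp, v in GLS_ORACLE["variances"].items():
            assert fit.variances[grp] == pytest.approx(v, rel=1e-6)
        eq = fit_hetero_oneway(y, g, equal_var=True)
        assert eq.f == pytest.approx(GLS_ORACLE["equal_var_F"], rel=1e-6)
        assert eq.p == pytest.approx(GLS_ORACLE["equal_var_p"], rel=1e-4)

    def test_equal_var_fit_matches_scipy_anova(self):
        rng = np.random.default_rng(3)
        samples = [rng.normal(m, 1.0, 7) for m in (0.0, 0.3, 1.1, 0.2)]
        y = np.concatenate(samples)
        g = np.repeat(list("wxyz"), 7)
        fit = fit_hetero_oneway(y, g, equal_var=True)
        f_ref, p_ref = stats.f_oneway(*samples)
        assert fit.f == pytest.approx(f_ref, rel=1e-6)
        assert fit.p == pytest.approx(p_ref, rel=1e-6)

    def test_reml_variances_recover_truth_on_large_samples(self):
        rng = np.random.default_rng(42)
        truth = {"a": 1.0, "b": 4.0, "c": 0.25}
        y, g = [], []
        for lab, var in truth.items():
            y += list(rng.normal(0.0, np.sqrt(var), 200))
            g += [lab] * 200
        fit = fit_hetero_oneway(np.array(y), np.array(g))
        for lab, var in truth.items():
            # Monte-Carlo error of a variance at n=200 is ~var*sqrt(2/199)
            assert fit.variances[lab] == pytest.approx(var, rel=0.35)

    def test_group_with_single_observation_rejected(self):
        with pytest.raises(DataError):
            fit_hetero_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_estimator_wrapper_exposes_fitted_attributes(self):
        y, g = _oracle_data()
        est = HeteroscedasticOneWay().fit(g, y)
        assert est.f_ == pytest.approx(GLS_ORACLE["F"], rel=1e-6)
        assert set(est.group_means_) == {"g1", "g2", "g3"}
        assert est.get_params()["equal_var"] is False


class TestTukey:
    def test_separated_groups_significant_with_distinct_letters(self):
        fit = fit_hetero_oneway([0, 1, 2, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        table = tukey_pairwise(fit)
        assert table.loc[0, "p_adj"] < 0.001
        letters = table.attrs["letters"]
        assert letters["a"] != letters["b"]

    def test_identical_groups_share_a_letter(self):
        fit = fit_hetero_oneway([5.0] * 10, ["a", "b"] * 5)
        table = tukey_pairwise(fit)
        assert table["p_adj"].iloc[0] == pytest.approx(1.0)
        letters = table.attrs["letters"]
        assert letters["a"] == letters["b"]

    def test_two_same_one_apart_letter_pattern(self):
        rng = np.random.default_rng(1)
        y = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(10, 1, 10)]
        )
        g = np.repeat(["g1", "g2", "g3"], 10)
        table = tukey_pairwise(fit_hetero_oneway(y, g))
        letters = table.attrs["letters"]
        assert letters["g1"] == letters["g2"]
        assert letters["g3"] != letters["g1"]

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 40)
        g = np.repeat(list("abcd"), 10)
        table = tukey_pairwise(fit_hetero_oneway(y, g))
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()

    def test_satterthwaite_df_between_min_and_pooled(self):
        y, g = _oracle_data()
        table = tukey_pairwise(fit_hetero_oneway(y, g))
        for _, row in table.iterrows():
            assert 1.0 < row["df"] < len(y)

    def test_pairwise_agrees_with_two_sample_welch(self):
        """Each pair's t and raw p match an independent Welch test."""
        y, g = _oracle_data()
        table = tukey_pairwise(fit_hetero_oneway(y, g))
        for _, row in table.iterrows():
            a = y[g == row["group_1"]]
            b = y[g == row["group_2"]]
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert row["t"] == pytest.approx(ref.statistic, rel=1e-9)
            assert row["p_raw"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestCompactLetters:
    def test_chain_pattern(self):
        # a~b and b~c non-significant, a vs c significant: letters ab overlap
        means = {"a": 0.0, "b": 1.0, "c": 2.0}
        letters = compact_letter_display(["a", "b", "c"], means, {("a", "c")})
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_all_distinct(self):
        means = {"a": 0.0, "b": 1.0, "c": 2.0}
        sig = {("a", "b"), ("a", "c"), ("b", "c")}
        letters = compact_letter_display(["a", "b", "c"], means, sig)
        assert len({letters[k] for k in "abc"}) == 3


class TestWelchT:
    def test_equal_means_give_zero(self):
        res = welch_t(1.0, 0.1, 5, 1.0, 0.2, 5)
        assert res.t == 0.0

    def test_leaf_nitrogen_footnote_example(self):
        # branch-collected vs ground-collected leaf N: 1.58 +- 0.05 (n=5)
        # vs 1.62 +- 0.13 (n=3); printed t = -0.28 from unrounded data
        res = welch_t(1.58, 0.05, 5, 1.62, 0.13, 3)
        assert abs(res.t - (-0.28)) <= 0.02
        assert res.df < 5

    def test_doubling_ses_halves_t(self):
        r1 = welch_t(1.0, 0.1, 6, 2.0, 0.2, 6)
        r2 = welch_t(1.0, 0.2, 6, 2.0, 0.4, 6)
        assert r2.t == pytest.approx(r1.t / 2)

    def test_zero_se_rejected(self):
        with pytest.raises(ValidationError):
            welch_t(1.0, 0.0, 5, 2.0, 0.1, 5)


class TestTraitRegression:
    def test_collinear_points_give_perfect_fit(self):
        fit = regress_effect_on_trait([2.0, 4.0, 6.0], [1.0, 2.0, 3.0],
                                      log_transform=False)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_flat_response_gives_zero_f(self):
        fit = regress_effect_on_trait([3.0, 3.0, 3.0, 3.0], [1.0, 2.0, 3.0, 4.0],
                                      log_transform=False)
        assert fit.f == 0.0
        assert fit.p == 1.0

    def test_simulated_positive_dependence_detected(self):
        """Effects generated with a positive dependence on a nutrient
        predictor yield a positive slope significant at the generating
        effect size."""
        rng = np.random.default_rng(21)
        p_conc = rng.uniform(0.04, 0.09, 20)
        effects = 0.2 + 8.0 * p_conc + rng.normal(0, 0.05, 20)
        fit = regress_effect_on_trait(effects, p_conc, log_transform=True)
        assert fit.slope > 0
        assert fit.p < 0.05
        assert fit.transform == "log-log"

    def test_nonpositive_predictor_under_log_is_error_listing_rows(self):
        with pytest.raises(ValidationError, match=r"\[1\]"):
            regress_effect_on_trait([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])

    def test_negative_effects_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="untransformed"):
            fit = regress_effect_on_trait([1.0, -0.5, 2.0, 1.5], [1.0, 2.0, 3.0, 4.0])
        assert fit.transform == "log-x"

    def test_estimator_wrapper(self):
        est = TraitEffectRegression(log_transform=False).fit(
            [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        )
        assert est.slope_ == pytest.approx(2.0)
        assert est.r2_ == pytest.approx(1.0)


class TestDiversityLossAnova:
    def test_focal_subset_pools_richness_levels(self, paper_metrics):
        fit, pairwise = diversity_loss_anova(
            paper_metrics, ("A", "C", "Q"), "normalized_mass_loss"
        )
        # monocultures A/C/Q, pairs AC/AQ/CQ, triple ACQ -> 3 richness levels
        assert set(fit.labels) == {"1", "2", "3"}
        assert fit.df_num == 2
        assert set(pairwise.attrs["letters"]) == {"1", "2", "3"}

    def test_full_pool_has_four_levels(self, paper_metrics):
        fit, _ = diversity_loss_anova(
            paper_metrics, ("A", "C", "Q", "I"), "normalized_mass_loss"
        )
        assert fit.df_num == 3
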