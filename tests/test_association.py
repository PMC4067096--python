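"""Derived-variable coding and the adjusted statistical suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pigmentscore.association import (
    anova_oneway,
    combine_freckles,
    combine_sunburn,
    fit_linear_adjusted,
    fit_logistic_adjusted,
    lrt_interaction,
    quartile_bins,
    run_paper_suite,
    semipartial_r2,
    t_test_means,
    total_mole_count,
)
from pigmentscore.exceptions import (
    DegenerateBinsError,
    InsufficientDataError,
    RankDeficiencyError,
    SchemaError,
    ValidationError,
)

NA = np.nan


class TestFreckleCoding:
    @pytest.mark.parametrize(
        "f49,f61,expected",
        [
            (0, 1, 1),          # a freckle at any age counts
            (1, NA, 1),
            (1, 0, 1),
            (0, 0, 0),
            (NA, 0, 0),         # valid later response fills a missing earlier one
            (NA, 1, 1),
            (0, NA, NA),        # freckle-free early, unobserved later: unknown
            (NA, NA, NA),
        ],
    )
    def test_truth_table(self, f49, f61, expected):
        out = combine_freckles(pd.Series([f49]), pd.Series([f61]))
        if np.isnan(expected):
            assert np.isnan(out.iloc[0])
        else:
            assert out.iloc[0] == expected

    def test_non_binary_code_rejected(self):
        with pytest.raises(ValidationError):
            combine_freckles(pd.Series([2.0]), pd.Series([0.0]))


class TestSunburnCoding:
    def _frame(self, row):
        return pd.DataFrame([row], columns=[f"s{k}" for k in range(6)])

    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0, 0, 0, 0, 0, 0), 0),
            ((0, NA, 0, 0, 1, 0), 1),   # any occurrence dominates missingness
            ((0, NA, 0, 0, 0, 0), NA),  # burn-free but incompletely observed
            ((1, NA, NA, NA, NA, NA), 1),
        ],
    )
    def test_any_occurrence_rule(self, row, expected):
        out = combine_sunburn(self._frame(row))
        if np.isnan(expected):
            assert np.isnan(out.iloc[0])
        else:
            assert out.iloc[0] == expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValidationError):
            combine_sunburn(pd.DataFrame([[0, 1]]))


class TestQuartiles:
    def test_uniform_counts_split_evenly(self):
        labels, ranges = quartile_bins(pd.Series(range(1, 9)))
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
        assert ranges[0] == "Q1 (1-2)"

    def test_ties_go_to_the_lower_bin(self):
        values = pd.Series([1, 5, 5, 5, 5, 5, 9, 10])
        labels, _ = quartile_bins(values)
        # the median mass of fives is <= both the 25th and 50th percentiles
        assert (labels[values == 5] != "Q3").all()
        # brute-force oracle: a value equal to a cut point takes the lower label
        cuts = np.percentile(values, [25, 50, 75])
        for v, lab in zip(values, labels):
            expected = "Q" + str(1 + int(np.sum(v > cuts)))
            assert lab == expected

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            quartile_bins(pd.Series([1, 2, 3]))

    def test_degenerate_when_all_equal(self):
        with pytest.raises(DegenerateBinsError):
            quartile_bins(pd.Series([4, 4, 4, 4, 4]))


class TestMoleCount:
    def test_sum_and_zero(self):
        assert total_mole_count(5, 7) == 12.0
        assert total_mole_count(0, 0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            total_mole_count(-1, 2)


class TestLinear:
    def test_exact_fit_has_zero_ci_width(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"y": 1 + 2 * x, "x": x})
        res = fit_linear_adjusted(data, "y", "x")
        assert res.effect == pytest.approx(2.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-8)
        assert res.model_r2 == pytest.approx(1.0)

    def test_hand_solved_slope(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1.0, 3.0, 6.0]})
        res = fit_linear_adjusted(data, "y", "x")
        assert res.effect == pytest.approx(2.5)

    def test_duplicated_exposure_is_rank_deficient(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"x": rng.normal(size=20)})
        data["y"] = data["x"] + rng.normal(size=20)
        data["x2"] = data["x"]
        with pytest.raises(RankDeficiencyError, match="x2"):
            fit_linear_adjusted(data, "y", "x", ["x2"])

    def test_complete_case_count_reported(self):
        data = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, np.nan, 5, 6, 7, 8], "x": np.arange(8.0)}
        )
        res = fit_linear_adjusted(data, "y", "x")
        assert res.n == 7


class TestLogistic:
    def test_two_by_two_matches_closed_form_odds_ratio(self):
        # cells (a, b, c, d) = (10, 20, 30, 40): log OR = ln(ad/bc) = ln(2/3)
        y = [1] * 10 + [0] * 20 + [1] * 30 + [0] * 40
        x = [1] * 30 + [0] * 70
        res = fit_logistic_adjusted(pd.DataFrame({"y": y, "x": x}), "y", "x")
        assert res.effect == pytest.approx(np.log((10 * 40) / (20 * 30)), abs=1e-5)
        assert res.odds_ratio == pytest.approx(2 / 3, abs=1e-4)

    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"y": rng.binomial(1, 0.4, 4000), "x": rng.normal(size=4000)}
        )
        res = fit_logistic_adjusted(data, "y", "x")
        assert abs(res.effect) < 3 * (res.ci_high - res.effect) / 1.96

    def test_single_class_outcome_rejected(self):
        data = pd.DataFrame({"y": [1.0] * 10, "x": np.arange(10.0)})
        with pytest.raises(ValidationError, match="single class"):
            fit_logistic_adjusted(data, "y", "x")


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # SSB = 13.5, SSW = 4, df (1, 4): F = 13.5
        res = anova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(13.5)
        assert res.p_value == pytest.approx(0.0214, abs=2e-3)
        assert res.groups.loc["a", "mean"] == pytest.approx(2.0)
        assert res.groups.loc["b", "n"] == 3

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError, match="singleton"):
            anova_oneway([1, 2, 3], ["a", "a", "b"])

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        groups = np.repeat(list("abcde"), 20)
        for _ in range(400):
            ps.append(anova_oneway(rng.normal(size=100), groups).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestTTest:
    def test_equal_samples(self):
        res = t_test_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_difference(self):
        res = t_test_means([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.difference == pytest.approx(3.0)
        # Welch on equal variances coincides with the pooled computation
        se = np.sqrt(1.0 / 3 + 1.0 / 3)
        t = 3.0 / se
        assert res.p_value == pytest.approx(2 * stats.t.sf(t, 4), abs=1e-9)
        assert res.ci_low < 3.0 < res.ci_high

    def test_singleton_rejected(self):
        with pytest.raises(ValidationError):
            t_test_means([1.0], [2.0, 3.0])

    def test_degenerate_equal_constants(self):
        res = t_test_means([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0


class TestLrt:
    def test_zero_product_column_gives_null_result(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"x": rng.normal(size=50), "m": np.zeros(50)})
        data["y"] = data["x"] + rng.normal(size=50)
        res = lrt_interaction(data, "y", "x", "m")
        assert res.lrt_statistic == 0.0 and res.p_value == 1.0

    def test_statistic_nonnegative_and_matches_wald_at_large_n(self):
        rng = np.random.default_rng(3)
        n = 4000
        data = pd.DataFrame({"x": rng.normal(size=n), "m": rng.binomial(1, 0.5, n)})
        data["y"] = data["x"] + 0.15 * data["x"] * data["m"] + rng.normal(size=n)
        res = lrt_interaction(data, "y", "x", "m")
        assert res.lrt_statistic >= 0
        import statsmodels.api as sm

        x = sm.add_constant(
            pd.DataFrame({"x": data["x"], "m": data["m"], "xm": data["x"] * data["m"]})
        )
        wald = (sm.OLS(data["y"], x).fit().tvalues["xm"]) ** 2
        assert res.lrt_statistic == pytest.approx(float(wald), rel=0.05)

    def test_power_rises_with_effect_size(self):
        rng = np.random.default_rng(4)
        rates = []
        for beta in (0.0, 0.15, 0.4):
            hits = 0
            for _ in range(60):
                n = 400
                x = rng.normal(size=n)
                m = rng.binomial(1, 0.5, n)
                y = x + beta * x * m + rng.normal(size=n)
                res = lrt_interaction(
                    pd.DataFrame({"x": x, "m": m, "y": y}), "y", "x", "m"
                )
                hits += res.p_value < 0.05
            rates.append(hits / 60)
        assert rates[0] < rates[1] < rates[2]


class TestSemipartial:
    def test_orthogonal_exposure_equals_simple_r2(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x, z = x - x.mean(), z - z.mean()
        x = x - z * (x @ z) / (z @ z)  # centred and exactly orthogonal
        y = x + z + rng.normal(size=n)
        data = pd.DataFrame({"y": y, "x": x, "z": z})
        simple = np.corrcoef(y, x)[0, 1] ** 2
        assert semipartial_r2(data, "y", "x", ["z"]) == pytest.approx(simple, abs=1e-6)

    def test_copy_of_covariate_contributes_nothing(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=60)
        data = pd.DataFrame({"z": z, "x": z, "y": z + rng.normal(size=60)})
        assert semipartial_r2(data, "y", "x", ["z"]) == pytest.approx(0.0, abs=1e-10)

    def test_sequential_orthogonal_shares_sum_to_model_r2(self):
        rng = np.random.default_rng(7)
        n = 300
        # columns orthogonal to each other *and* to the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 3))]))
        q = q[:, 1:]
        data = pd.DataFrame(q, columns=["a", "b", "c"])
        data["y"] = q @ [1.0, 0.5, 0.2] + rng.normal(size=n)
        total = fit_linear_adjusted(data, "y", "a", ["b", "c"]).model_r2
        shares = (
            semipartial_r2(data, "y", "a", ["b", "c"])
            + semipartial_r2(data, "y", "b", ["a", "c"])
            + semipartial_r2(data, "y", "c", ["a", "b"])
        )
        assert shares == pytest.approx(total, abs=1e-8)


@pytest.fixture(scope="module")
def suite_inputs():
    import warnings

    from pigmentscore.io import derive_variables
    from pigmentscore.scores import compute_all_scores, load_score_definitions
    from pigmentscore.seasonal import deseasonalize
    from pigmentscore.simulate import GeneratorConfig, simulate_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate_cohort(GeneratorConfig(n=1500), seed=123)
        scores = compute_all_scores(sim.dosages, load_score_definitions())
        cohort = derive_variables(sim.cohort)
        habitual, _ = deseasonalize(cohort)
        cohort["deseasonalized_25ohd"] = habitual
    return cohort, scores


class TestSuite:
    def test_emits_expected_tables(self, suite_inputs):
        cohort, scores = suite_inputs
        tables = run_paper_suite(cohort, scores)
        assert {"reflectance", "vitamin_d", "vitamin_d_mutual", "categories",
                "sex_stratified", "interactions"} <= set(tables)
        vd = tables["vitamin_d"]
        assert set(vd.index) == {"skin_colour", "tanning", "freckling"}
        assert ((vd["ci_low"] <= vd["effect"]) & (vd["effect"] <= vd["ci_high"])).all()
        assert (vd["semipartial_r2"].between(0, 1)).all()

    def test_missing_pcs_raise_schema_error(self, suite_inputs):
        cohort, scores = suite_inputs
        with pytest.raises(SchemaError, match="pc"):
            run_paper_suite(cohort.drop(columns=["pc3"]), scores)

    def test_mutual_adjustment_isolates_the_directly_acting_score(self):
        """With correlated scores whose direct effect loads on skin colour
        only, adjusting each score for the other two leaves an association
        for the skin colour score alone."""
        import warnings

        from pigmentscore.scores import compute_all_scores, load_score_definitions
        from pigmentscore.seasonal import deseasonalize
        from pigmentscore.simulate import (
            EffectSpec,
            GeneratorConfig,
            expected_score_covariance,
            simulate_cohort,
        )

        definitions = load_score_definitions()
        sigma = expected_score_covariance(definitions, GeneratorConfig().allele_freqs)
        direct = 1.0  # nmol/l per skin-colour unit, nothing on the others
        marginals = {
            name: float(sigma.loc[name, "skin_colour"] * direct / sigma.loc[name, name])
            for name in sigma.index
        }
        config = GeneratorConfig(
            n=20_000,
            effects=EffectSpec(vitd_marginal=marginals),
            pc_allele_shift=0.0,
            pc_vitd_effect=0.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = simulate_cohort(config, seed=31)
            data = sim.cohort.join(compute_all_scores(sim.dosages, definitions))
            habitual, _ = deseasonalize(data)
            data["deseasonalized_25ohd"] = habitual
        pcs = [f"pc{i}" for i in range(1, 11)]
        estimates = {}
        for s in sigma.index:
            others = [o for o in sigma.index if o != s]
            fit = fit_linear_adjusted(
                data, "deseasonalized_25ohd", s,
                ["age_at_draw_months", "sex", *pcs, *others],
            )
            estimates[s] = fit
        assert estimates["skin_colour"].effect == pytest.approx(direct, abs=0.25)
        assert estimates["skin_colour"].p_value < 1e-6
        for other in ("tanning", "freckling"):
            assert abs(estimates[other].effect) < 0.2


def test_wald_interval_coverage_is_nominal():
    """95% Wald CIs cover the injected slope in about 95% of 1000 simulated
    data sets."""
    rng = np.random.default_rng(8)
    covered = 0
    for _ in range(1000):
        x = rng.normal(size=100)
        y = 2.0 * x + rng.normal(size=100)
        res = fit_linear_adjusted(pd.DataFrame({"x": x, "y": y}), "y", "x")
        covered += res.ci_low <= 2.0 <= res.ci_high
    assert 0.93 <= covered / 1000 <= 0.97
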