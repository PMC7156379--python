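import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icbsex import propensity, synth
from icbsex.dataio import FeatureMatrix
from icbsex.propensity import (
    PropensityError,
    balance_report,
    bh_adjust,
    discrete_feature_test,
    eligible_cohorts,
    fit_propensity,
    matching_weights,
    sex_bias_screen,
    standardized_difference,
    weighted_feature_test,
)
from tests.conftest import COVARIATES


def tiny_cohort(n_f, n_m):
    n = n_f + n_m
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "sex": ["female"] * n_f + ["male"] * n_m,
            "age": np.linspace(40, 80, n),
        }
    )


class TestEligibility:
    def test_below_threshold_excluded(self):
        cohorts = {"A": tiny_cohort(19, 200), "B": tiny_cohort(20, 20)}
        kept = eligible_cohorts(cohorts, min_per_group=20)
        assert set(kept) == {"B"}

    def test_threshold_one_keeps_two_sex_cohorts(self):
        kept = eligible_cohorts({"A": tiny_cohort(1, 1)}, min_per_group=1)
        assert set(kept) == {"A"}


class TestFitPropensity:
    def test_null_covariates_give_scores_near_prevalence(self):
        rng = np.random.default_rng(3)
        n = 4000
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "sex": np.where(rng.random(n) < 0.4, "female", "male"),
                "age": rng.normal(60, 10, n),
                "purity": rng.beta(5, 2, n),
            }
        )
        model = fit_propensity(cohort, ["age", "purity"])
        assert model.scores.mean() == pytest.approx(0.4, abs=0.03)
        assert model.scores.std() < 0.05

    def test_single_binary_covariate_matches_2x2_log_odds(self):
        # counts: smokers 30F/10M, non-smokers 20F/40M
        rows = (
            [("female", "yes")] * 30 + [("male", "yes")] * 10
            + [("female", "no")] * 20 + [("male", "no")] * 40
        )
        cohort = pd.DataFrame(rows, columns=["sex", "smoker"])
        cohort["patient_id"] = [f"p{i}" for i in range(len(cohort))]
        model = fit_propensity(cohort, ["smoker"])
        # reference level is the most frequent ('no'); coefficient = log OR
        expected = math.log((30 / 10) / (20 / 40))
        assert model.coefficients["smoker[yes]"] == pytest.approx(expected, abs=1e-6)
        assert model.coefficients["intercept"] == pytest.approx(math.log(20 / 40), abs=1e-6)

    def test_matches_statsmodels_logit(self, confounded_cohort):
        import statsmodels.api as sm

        cohort, _, _ = confounded_cohort
        model = fit_propensity(cohort, ["age", "purity"])
        age = cohort["age"]
        purity = cohort["purity"]
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                (age - age.mean()) / age.std(ddof=1),
                (purity - purity.mean()) / purity.std(ddof=1),
            ]
        )
        ref = sm.Logit((cohort["sex"] == "female").astype(float), X).fit(disp=0)
        np.testing.assert_allclose(model.coefficients.to_numpy(), ref.params, atol=1e-6)

    def test_parameter_recovery_at_large_n(self):
        spec = synth.CohortSimSpec(
            n=5000, confounder_effects={"age": 0.7}, seed=9
        )
        cohort, _, _ = synth.simulate_cohort(spec)
        model = fit_propensity(cohort, ["age"])
        # standardized-age coefficient should recover the generating 0.7
        se_approx = 1.0 / math.sqrt(5000 * 0.25)
        assert abs(model.coefficients["age"] - 0.7) < 3 * se_approx

    def test_perfect_separation_triggers_ridge(self, caplog):
        cohort = tiny_cohort(20, 20)
        cohort["age"] = [1.0] * 20 + [0.0] * 20  # separates sexes exactly
        with caplog.at_level("WARNING"):
            model = fit_propensity(cohort, ["age"])
        assert model.ridged
        assert ((model.scores > 0) & (model.scores < 1)).all()


class TestMatchingWeights:
    def test_equipoise_gives_weight_one(self):
        model = _model_from_scores([0.5, 0.5], [1, 0])
        np.testing.assert_allclose(matching_weights(model), [1.0, 1.0])

    def test_hand_arithmetic(self):
        model = _model_from_scores([0.3, 0.3], [1, 0])
        np.testing.assert_allclose(matching_weights(model), [1.0, 0.3 / 0.7])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=30), st.data())
    def test_weights_bounded_in_unit_interval(self, scores, data):
        groups = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        w = matching_weights(_model_from_scores(scores, groups))
        assert ((w > 0) & (w <= 1.0)).all()


def _model_from_scores(scores, group):
    idx = pd.Index([f"p{i}" for i in range(len(scores))], name="patient_id")
    return propensity.PropensityModel(
        coefficients=pd.Series(dtype=float),
        scores=pd.Series(scores, index=idx, dtype=float),
        group=pd.Series(group, index=idx, dtype=int),
        covariates=[],
    )


class TestStandardizedDifference:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        z = np.array([1, 1, 1, 0, 0, 0])
        assert standardized_difference(x, z) == pytest.approx(0.0)

    def test_hand_arithmetic_unit_sds(self, rng):
        # construct groups with sample means 2 / 1 and sample SD exactly 1
        base = rng.normal(size=60)
        base = (base - base.mean()) / base.std(ddof=1)
        x = np.concatenate([base + 2.0, base + 1.0])
        z = np.repeat([1, 0], 60)
        assert standardized_difference(x, z) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_covariate_errors_when_means_differ(self):
        with pytest.raises(PropensityError, match="degenerate"):
            standardized_difference([1, 1, 2, 2], [1, 1, 0, 0])

    def test_weighting_restores_balance(self, confounded_cohort):
        cohort, _, _ = confounded_cohort
        model = fit_propensity(cohort, COVARIATES)
        w = matching_weights(model)
        report = balance_report(cohort, model, w)
        age = report.table.loc["age"]
        assert abs(age["smd_before"]) > 0.1  # confounded by construction
        assert abs(age["smd_after"]) < 0.1
        assert report.table["smd_after"].abs().max() < 0.1


class TestBalanceReport:
    def test_no_confounding_balanced_before_and_after(self):
        spec = synth.CohortSimSpec(n=2000, confounder_effects={}, seed=21)
        cohort, _, _ = synth.simulate_cohort(spec)
        model = fit_propensity(cohort, ["age", "purity"])
        report = balance_report(cohort, model, matching_weights(model))
        assert report.table["smd_before"].abs().max() < 0.1
        assert report.table["smd_after"].abs().max() < 0.1

    def test_identical_score_distributions_overlap_one(self):
        scores = pd.Series(
            np.tile(np.linspace(0.2, 0.8, 50), 2),
            index=pd.Index([f"p{i}" for i in range(100)], name="patient_id"),
        )
        group = pd.Series(
            np.repeat([1, 0], 50), index=scores.index
        )
        assert propensity.overlap_coefficient(scores, group) == pytest.approx(1.0)


class TestWeightedFeatureTest:
    def test_unit_weights_reduce_to_mean_difference(self, rng):
        x = rng.normal(size=100)
        z = rng.binomial(1, 0.5, 100).astype(float)
        w = np.ones(100)
        beta, _, _ = weighted_feature_test(x, z, w)
        assert beta == pytest.approx(x[z == 1].mean() - x[z == 0].mean(), abs=1e-12)

    def test_matches_statsmodels_wls_hc0(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=200)
        z = rng.binomial(1, 0.5, 200).astype(float)
        w = rng.uniform(0.2, 1.0, 200)
        beta, se, p = weighted_feature_test(x, z, w)
        X = sm.add_constant(z)
        fit = sm.WLS(x, X, weights=w).fit(cov_type="HC0")
        assert beta == pytest.approx(fit.params[1], abs=1e-10)
        assert se == pytest.approx(fit.bse[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_missing_values_dropped_not_zeroed(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 4.0])
        z = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        beta, _, _ = weighted_feature_test(x, z, np.ones(6))
        assert beta == pytest.approx(1.5 - 3.5)

    def test_all_missing_feature_flagged_untestable(self):
        with pytest.raises(PropensityError, match="untestable"):
            weighted_feature_test([np.nan, np.nan], [1, 0], [1, 1])

    def test_confounder_removal(self):
        """The module's core property: the matching-weight test stays near
        the nominal level on confounded null features while the unweighted
        test rejects far above it (small-scale check; the full 2000-rep
        calibration lives in the acceptance suite)."""
        reps, rej_w, rej_u = 300, 0, 0
        seeds = np.random.SeedSequence(99).generate_state(reps) % (2**31)
        for s in seeds:
            spec = synth.default_cohort_spec(int(s), n_null=1, n_signal=0)
            cohort, fm, _ = synth.simulate_cohort(spec)
            model = fit_propensity(cohort, COVARIATES)
            w = matching_weights(model).to_numpy()
            x = fm.values.reindex(model.scores.index)["null_01"].to_numpy()
            z = model.group.to_numpy()
            rej_w += weighted_feature_test(x, z, w)[2] < 0.05
            rej_u += weighted_feature_test(x, z, np.ones_like(w))[2] < 0.05
        assert rej_u / reps > 0.10
        assert rej_w / reps < 0.10


class TestDiscreteFeatureTest:
    def test_zero_cell_handled(self):
        x = np.array([1.0, 1, 1, 0, 0, 0])
        z = np.array([1.0, 1, 1, 0, 0, 0])
        odds, p = discrete_feature_test(x, z)
        assert 0 <= p <= 1

    def test_independent_indicator_near_nominal(self, rng):
        rejections, reps = 0, 500
        for _ in range(reps):
            z = rng.binomial(1, 0.5, 120).astype(float)
            x = rng.binomial(1, 0.3, 120).astype(float)
            rejections += discrete_feature_test(x, z)[1] < 0.05
        # Fisher is conservative for small tables; bounded above by nominal
        assert rejections / reps <= 0.065


class TestBH:
    def test_hand_step_up_example(self):
        adj = bh_adjust([0.005, 0.011, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.022, 0.02 * 4 / 3, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_equal_ps_map_to_themselves(self):
        np.testing.assert_allclose(bh_adjust([0.07] * 5), [0.07] * 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        p = np.asarray(ps)
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def screen_run():
    spec = synth.default_cohort_spec(seed=17)
    cohort, fm, truth = synth.simulate_cohort(spec)
    results, summary, balances = sex_bias_screen(
        {"cohortA": cohort}, {"cohortA": fm}, COVARIATES, min_per_group=20
    )
    return results, summary, balances, truth


class TestScreen:
    def test_direction_coding_follows_female_shift(self, screen_run):
        results, _, _, truth = screen_run
        signal = [r for r in results if r.feature.startswith("signal")]
        assert signal, "signal features missing from screen output"
        assert all(r.direction == "female-bias" for r in signal if r.p_value < 0.05)

    def test_signal_features_detected_at_fdr(self, screen_run):
        results, _, _, _ = screen_run
        hits = {r.feature for r in results if r.fdr < 0.2}
        signal_hits = {f for f in hits if f.startswith("signal")}
        assert len(signal_hits) >= 4  # >=4 of the 5 true half-SD shifts

    def test_summary_counts_consistent(self, screen_run):
        results, summary, _, _ = screen_run
        row = summary.loc["cohortA"]
        n_f = sum(1 for r in results if r.fdr < 0.2 and r.direction == "female-bias")
        n_m = sum(1 for r in results if r.fdr < 0.2 and r.direction == "male-bias")
        assert (row["n_female_biased"], row["n_male_biased"]) == (n_f, n_m)
        assert row["score"] == n_f - n_m

    def test_balance_reported_per_cohort(self, screen_run):
        _, _, balances, _ = screen_run
        assert "cohortA" in balances
        assert 0 < balances["cohortA"].overlap <= 1

    def test_patient_order_and_covariate_scale_invariance(self):
        spec = synth.default_cohort_spec(seed=23, n_null=5, n_signal=2)
        cohort, fm, _ = synth.simulate_cohort(spec)
        res1, _, _ = sex_bias_screen({"c": cohort}, {"c": fm}, COVARIATES)
        shuffled = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        rescaled = shuffled.copy()
        rescaled["age"] = rescaled["age"] * 12.0 + 7.0  # affine rescale
        res2, _, _ = sex_bias_screen({"c": rescaled}, {"c": fm}, COVARIATES)
        p1 = {r.feature: r.p_value for r in res1}
        p2 = {r.feature: r.p_value for r in res2}
        assert p1.keys() == p2.keys()
        for feat in p1:
            assert p1[feat] == pytest.approx(p2[feat], rel=1e-6), feat

    def test_no_signal_cohort_scores_near_zero(self):
        spec = synth.default_cohort_spec(seed=31, n_null=20, n_signal=0)
        cohort, fm, _ = synth.simulate_cohort(spec)
        _, summary, _ = sex_bias_screen({"c": cohort}, {"c": fm}, COVARIATES)
        assert abs(int(summary.loc["c", "score"])) <= 2

    def test_discrete_features_use_fisher(self):
        spec = synth.default_cohort_spec(seed=41, n_null=3, n_signal=0)
        cohort, fm, _ = synth.simulate_cohort(spec)
        rng = np.random.default_rng(5)
        vals = fm.values.copy()
        vals["mut_PBRM1"] = rng.binomial(1, 0.2, len(vals)).astype(float)
        fm2 = FeatureMatrix(values=vals, discrete=frozenset({"mut_PBRM1"}))
        results, _, _ = sex_bias_screen({"c": cohort}, {"c": fm2}, COVARIATES)
        tests = {r.feature: r.test for r in results}
        assert tests["mut_PBRM1"] == "fisher"
        assert all(t == "weighted-linear" for f, t in tests.items() if f != "mut_PBRM1")


def test_weighting_reduces_smd_across_cohorts():
    """Balance property: matching weights push confounded covariates below
    |SMD| = 0.1 in nearly all synthetic cohorts (50-cohort spot check; the
    100-cohort version runs in the acceptance suite)."""
    ok = 0
    reps = 50
    seeds = np.random.SeedSequence(2024).generate_state(reps) % (2**31)
    for s in seeds:
        spec = synth.default_cohort_spec(int(s), n_null=1, n_signal=0)
        cohort, _, _ = synth.simulate_cohort(spec)
        model = fit_propensity(cohort, COVARIATES)
        report = balance_report(cohort, model, matching_weights(model))
        ok += report.table["smd_after"].abs().max() < 0.1
    assert ok / reps >= 0.9
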