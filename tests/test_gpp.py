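"""Feature hygiene, shadow-feature importance, stepwise logistic fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtrkit.gpp import (
    FeatureMatrix,
    assess_feature_importance,
    evaluate_auc,
    fit_logistic_model,
    GeneModel,
    impute_missing_scores,
    prune_near_zero_variance,
    prune_pairwise_correlated,
    score_gpp,
    score_gpp_frame,
    select_gene_model,
)
from mtrkit.simulate import FeatureSpec, simulate_feature_matrix


class TestImputation:
    def test_median_of_two(self):
        m = FeatureMatrix(scores=pd.DataFrame({"f": [0.2, 0.4, np.nan]}))
        out = impute_missing_scores(m)
        assert out.scores["f"].tolist() == pytest.approx([0.2, 0.4, 0.3])

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"f": [0.1, 0.9]})
        out = impute_missing_scores(FeatureMatrix(scores=df))
        pd.testing.assert_frame_equal(out.scores, df)

    def test_per_gene_medians(self):
        # gene A median 0.2, gene B median 0.8 — six-row fixture by hand
        scores = pd.DataFrame({"f": [0.1, 0.3, np.nan, 0.7, 0.9, np.nan]})
        genes = pd.Series(["A", "A", "A", "B", "B", "B"])
        out = impute_missing_scores(FeatureMatrix(scores=scores, genes=genes))
        assert out.scores["f"].tolist() == pytest.approx([0.1, 0.3, 0.2, 0.7, 0.9, 0.8])

    def test_entirely_missing_feature_in_gene_raises(self):
        scores = pd.DataFrame({"f": [np.nan, np.nan, 0.5]})
        genes = pd.Series(["A", "A", "B"])
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing_scores(FeatureMatrix(scores=scores, genes=genes))


class TestNearZeroVariance:
    def test_constant_column_flagged(self):
        df = pd.DataFrame({"c": [0.5] * 100, "ok": np.linspace(0, 1, 100)})
        assert prune_near_zero_variance(df) == ["ok"]

    def test_ninety_ten_two_values_flagged(self):
        col = np.array([0.0] * 900 + [1.0] * 100)
        df = pd.DataFrame({"bad": col, "ok": np.linspace(0, 1, 1000)})
        # ratio 9 > 4 and 2/1000 distinct < 5%
        assert prune_near_zero_variance(df) == ["ok"]

    def test_uniform_continuous_retained(self):
        df = pd.DataFrame({"ok": np.linspace(0, 1, 50)})
        assert prune_near_zero_variance(df) == ["ok"]

    def test_high_ratio_but_many_distinct_retained(self):
        # dominant value yet >5% distinct values: only one criterion met
        col = np.concatenate([np.zeros(50), np.linspace(0.1, 1, 50)])
        df = pd.DataFrame({"f": col})
        assert prune_near_zero_variance(df) == ["f"]


class TestCorrelationPruning:
    def test_duplicated_column_pair(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.uniform(size=200)})
        kept = prune_pairwise_correlated(df)
        assert "c" in kept and len(kept) == 2

    def test_removes_member_with_larger_mean_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        a = x
        b = x + rng.normal(scale=0.3, size=500)  # |r(a,b)| ~ 0.95
        c = 0.5 * a + rng.normal(scale=1.0, size=500)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        corr = df.corr().abs()
        assert corr.loc["a", "b"] > 0.75
        # the member of the worst pair with the larger mean |r| must go
        mean_a = (corr.loc["a", "b"] + corr.loc["a", "c"]) / 2
        mean_b = (corr.loc["a", "b"] + corr.loc["b", "c"]) / 2
        removed = "a" if mean_a >= mean_b else "b"
        kept = prune_pairwise_correlated(df)
        assert kept == [f for f in ["a", "b", "c"] if f != removed]

    def test_all_low_correlation_is_identity(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(size=(300, 4)), columns=list("wxyz"))
        assert prune_pairwise_correlated(df) == list("wxyz")


class TestImportance:
    @pytest.fixture(scope="class")
    def planted_report(self):
        spec = [FeatureSpec("planted", 2.0)] + [FeatureSpec(f"n{i}") for i in range(4)]
        m = simulate_feature_matrix(200, 200, spec, seed=9)
        return assess_feature_importance(m, seed=9, runs=10, trees=60, vars_per_split=4)

    def test_planted_feature_informative(self, planted_report):
        assert planted_report.categories["planted"] in ("informative", "highly_informative")

    def test_noise_features_not_highly_informative(self, planted_report):
        for f in ("n0", "n1", "n2", "n3"):
            assert planted_report.categories[f] != "highly_informative"

    def test_highly_informative_subset_of_informative(self, planted_report):
        for f, cat in planted_report.categories.items():
            if cat == "highly_informative":
                assert f in planted_report.informative()

    def test_bitwise_reproducible_under_seed(self):
        spec = [FeatureSpec("planted", 2.0), FeatureSpec("n0")]
        m = simulate_feature_matrix(80, 80, spec, seed=4)
        a = assess_feature_importance(m, seed=4, runs=4, trees=30)
        b = assess_feature_importance(m, seed=4, runs=4, trees=30)
        assert np.array_equal(a.z_scores, b.z_scores)
        assert np.array_equal(a.shadow_max, b.shadow_max)

    def test_single_class_labels_raise(self):
        m = simulate_feature_matrix(10, 10, [FeatureSpec("f", 1.0)], seed=0)
        m.labels[:] = 1
        with pytest.raises(ValueError):
            assess_feature_importance(m, runs=2, trees=10)

    def test_missing_values_rejected(self):
        scores = pd.DataFrame({"f": [0.1, np.nan, 0.5, 0.2]})
        m = FeatureMatrix(scores=scores, labels=pd.Series([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="impute"):
            assess_feature_importance(m, runs=2, trees=10)


class TestModelSelection:
    def test_signal_feature_enters_and_lowers_aic(self):
        m = simulate_feature_matrix(
            400, 400, [FeatureSpec("strong", 2.0), FeatureSpec("noise")], seed=7
        )
        model = select_gene_model(m, ["strong", "noise"], include_mtr=False, gene_symbol="SIM")
        assert "strong" in model.coefficients
        start_aic = model.selection_trace[0]["aic"]
        accepted = [t for t in model.selection_trace if t.get("accepted")]
        assert accepted and accepted[0]["aic"] < start_aic

    def test_noise_rejected_by_stop_rule(self):
        """A pure-noise second feature survives the relative-likelihood bar
        only with probability ~0.5%; over replicates it is almost always cut."""
        rejected = 0
        for seed in range(6):
            m = simulate_feature_matrix(
                500, 500, [FeatureSpec("strong", 2.0), FeatureSpec("noise")], seed=seed
            )
            model = select_gene_model(m, ["strong", "noise"], include_mtr=False)
            rejected += "noise" not in model.coefficients
        assert rejected >= 5

    def test_duplicate_informative_feature_enters_once(self):
        m = simulate_feature_matrix(300, 300, [FeatureSpec("strong", 2.0)], seed=6)
        m.scores["twin"] = m.scores["strong"]
        model = select_gene_model(m, ["strong", "twin"], include_mtr=False)
        assert sorted(model.coefficients) == ["strong"]

    def test_include_mtr_places_mtr_in_model(self):
        m = simulate_feature_matrix(200, 200, [FeatureSpec("f", 1.5)], seed=5)
        # depleted codons (low MTR) enriched among cases
        mtr = pd.Series(
            np.where(m.labels == 1, 0.3, 0.9)
            + np.random.default_rng(0).normal(0, 0.05, len(m.labels)),
            index=m.scores.index,
        )
        m.mtr = mtr
        model = select_gene_model(m, ["f"], include_mtr=True)
        assert "MTR" in model.coefficients
        assert model.coefficients["MTR"] < 0  # lower MTR => more pathogenic

    def test_separation_falls_back_to_ridge(self):
        scores = pd.DataFrame({"f": np.concatenate([np.zeros(20), np.ones(20)])})
        labels = pd.Series(np.concatenate([np.zeros(20, int), np.ones(20, int)]))
        m = FeatureMatrix(scores=scores, labels=labels)
        model = select_gene_model(m, ["f"], include_mtr=False)
        assert model.used_ridge_fallback
        assert np.isfinite(model.coefficients.get("f", np.nan))

    def test_model_roundtrips_through_json_dict(self):
        m = simulate_feature_matrix(100, 100, [FeatureSpec("f", 2.0)], seed=3)
        model = select_gene_model(m, ["f"], include_mtr=False, gene_symbol="G")
        again = GeneModel.from_dict(model.to_dict())
        assert again.coefficients == model.coefficients
        assert again.intercept == model.intercept


class TestScoring:
    def test_zero_coefficients_give_half(self):
        model = GeneModel("G", intercept=0.0, coefficients={"f": 0.0})
        assert score_gpp(model, {"f": 0.7}) == pytest.approx(0.5)

    def test_linear_predictor_zero(self):
        model = GeneModel("G", intercept=-2.0, coefficients={"f": 4.0})
        assert score_gpp(model, {"f": 0.5}) == pytest.approx(0.5)

    def test_monotone_in_positive_feature(self):
        model = GeneModel("G", intercept=0.0, coefficients={"f": 3.0})
        xs = [score_gpp(model, {"f": v}) for v in (0.1, 0.5, 0.9)]
        assert xs == sorted(xs)
        assert all(0 < s < 1 for s in xs)

    def test_missing_feature_raises(self):
        model = GeneModel("G", intercept=0.0, coefficients={"f": 1.0})
        with pytest.raises(KeyError):
            score_gpp(model, {"g": 0.2})

    def test_frame_scoring_matches_scalar(self):
        model = GeneModel("G", intercept=-1.0, coefficients={"a": 2.0, "b": -1.0})
        frame = pd.DataFrame({"a": [0.1, 0.9], "b": [0.5, 0.2]})
        vec = score_gpp_frame(model, frame)
        for i in range(2):
            assert vec[i] == pytest.approx(score_gpp(model, frame.iloc[i].to_dict()))


class TestAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert evaluate_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_pair_enumeration_example(self):
        # cases {0.9, 0.8}, controls {0.7, 0.85}: 3 of 4 pairs won
        assert evaluate_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_equals_mann_whitney_u_over_n1n2(self):
        rng = np.random.default_rng(12)
        scores = rng.permutation(40).astype(float)  # tie-free
        labels = np.array([1] * 15 + [0] * 25)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert evaluate_auc(scores, labels) == pytest.approx(u / (15 * 25))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            evaluate_auc([0.1, 0.2], [1, 1])


class TestRecovery:
    def test_known_coefficients_recovered_within_wald_interval(self):
        """95% intervals from a correctly specified fit cover the generating
        coefficients in the large majority of replicates."""
        beta0, beta = -0.5, np.array([3.0, -2.0])
        n = 2000
        covered = np.zeros(2, dtype=int)
        n_reps = 8
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            X = rng.uniform(size=(n, 2))
            y = rng.random(n) < 1 / (1 + np.exp(-(beta0 + X @ beta)))
            m = FeatureMatrix(
                scores=pd.DataFrame(X, columns=["x1", "x2"]),
                labels=pd.Series(y.astype(int)),
            )
            model, ci = fit_logistic_model(m, ["x1", "x2"])
            assert ci is not None
            assert 0.55 < model.training_auc < 0.95
            for i in range(2):
                lo, hi = ci[i + 1]
                covered[i] += lo <= beta[i] <= hi
        assert all(covered >= n_reps - 2)
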