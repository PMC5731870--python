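import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliotex.evaluate import (
    ConfusionMatrix,
    auc_bootstrap_ci,
    compare_auc_bootstrap,
    confusion_metrics,
    covariate_adjusted_regression,
    evaluate_predictions,
    kruskal_wallis_balance,
    roc_auc,
    roc_curve_points,
    spearman_concordance,
)
from oracles import naive_auc


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_partial_separation_pairwise(self):
        # 4 pos-neg pairs, exactly one win: 1/4
        assert roc_auc([0.9, 0.2, 0.8, 0.1], [0, 0, 1, 1]) == 0.25

    def test_all_ties_half(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 12),
        seed=st.integers(0, 10**6),
        tie_prob=st.floats(0, 0.8),
    )
    def test_matches_pairwise_oracle(self, n, seed, tie_prob):
        r = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: r.integers(1, n)] = 1
        r.shuffle(labels)
        if labels.min() == labels.max():
            return
        # draw from a small value set to force ties
        scores = r.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
        if tie_prob < 0.4:
            scores = r.normal(size=n)
        assert roc_auc(scores, labels) == pytest.approx(naive_auc(scores, labels))


class TestBootstrapCI:
    def test_separated_sample_tight_interval(self):
        r = np.random.default_rng(0)
        scores = np.r_[r.normal(0, 0.1, 200), r.normal(10, 0.1, 200)]
        labels = np.r_[np.zeros(200, int), np.ones(200, int)]
        lo, hi = auc_bootstrap_ci(scores, labels, seed=1)
        assert lo >= 0.99 and hi <= 1.0

    def test_interval_contains_point_estimate(self):
        r = np.random.default_rng(3)
        scores = r.normal(size=80) + np.r_[np.zeros(40), np.ones(40)]
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        auc = roc_auc(scores, labels)
        for seed in range(5):
            lo, hi = auc_bootstrap_ci(scores, labels, n_boot=500, seed=seed)
            assert lo <= auc <= hi

    def test_deterministic_under_seed(self):
        r = np.random.default_rng(4)
        scores, labels = r.normal(size=40), np.r_[np.zeros(20, int), np.ones(20, int)]
        a = auc_bootstrap_ci(scores, labels, n_boot=300, seed=9)
        b = auc_bootstrap_ci(scores, labels, n_boot=300, seed=9)
        assert a == b

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="100"):
            auc_bootstrap_ci([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50)


class TestConfusionMetrics:
    def test_testing_cohort_worked_example(self):
        # printed testing matrix: TN=10, FN=6, FP=2, TP=16
        m = confusion_metrics(ConfusionMatrix(tp=16, fp=2, tn=10, fn=6))
        assert m["accuracy"] == pytest.approx(26 / 34)
        assert m["accuracy"] * 100 == pytest.approx(76.5, abs=0.05)
        assert m["sensitivity"] * 100 == pytest.approx(72.7, abs=0.05)
        assert m["specificity"] * 100 == pytest.approx(83.33, abs=0.005)
        assert m["fdr"] * 100 == pytest.approx(11.1, abs=0.05)
        assert m["accuracy_ci_low"] == pytest.approx(0.588, abs=5e-4)
        assert m["accuracy_ci_high"] == pytest.approx(0.893, abs=5e-4)

    def test_training_cohort_worked_example(self):
        # printed training matrix: TN=19, FN=1, FP=0, TP=15
        m = confusion_metrics(ConfusionMatrix(tp=15, fp=0, tn=19, fn=1))
        assert m["accuracy"] * 100 == pytest.approx(97.1, abs=0.05)
        assert m["sensitivity"] * 100 == pytest.approx(93.75, abs=0.005)
        assert m["specificity"] == 1.0
        assert m["fdr"] == 0.0

    def test_all_correct_boundary(self):
        m = confusion_metrics(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert m["accuracy"] == 1.0
        assert m["accuracy_ci_high"] == 1.0

    def test_empty_positive_prediction_flags_fdr(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(m["fdr"]) and m.get("fdr_undefined") == 1.0

    def test_from_predictions(self):
        cm = ConfusionMatrix.from_predictions([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_clopper_pearson_coverage(self):
        # n=34, p=0.75: the exact interval should cover >= 95% of draws
        r = np.random.default_rng(6)
        covered = 0
        n, p, reps = 34, 0.75, 2000
        ks = r.binomial(n, p, size=reps)
        from statsmodels.stats.proportion import proportion_confint

        for k in ks:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
            covered += lo <= p <= hi
        assert covered / reps >= 0.95


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_concordance([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman_concordance([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = spearman_concordance([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_concordance([1, 1, 1], [1, 2, 3])


class TestAdjustedRegression:
    def _covs(self, n, seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "age": r.normal(57, 12, n),
                "gender": r.choice(["F", "M"], n),
                "kps": r.choice([60, 70, 80, 90, 100], n),
                "flair_tumor_volume": r.normal(1.3e5, 2e4, n),
                "flair_total_intensity": r.normal(2e5, 3e4, n),
                "t1post_tumor_volume": r.normal(5e4, 1e4, n),
                "t1post_total_intensity": r.normal(8e4, 2e4, n),
            }
        )

    def test_strong_predictor_dominates(self):
        r = np.random.default_rng(101)
        pred = r.normal(size=100)
        p = covariate_adjusted_regression(pred, pred, self._covs(100, seed=1))
        assert p["model_prediction"] < 0.001
        assert p["model_prediction"] == min(p.values())

    def test_reports_exactly_the_eight_variables(self):
        r = np.random.default_rng(2)
        p = covariate_adjusted_regression(
            r.normal(size=50), r.normal(size=50), self._covs(50, seed=2)
        )
        assert list(p) == [
            "age", "gender", "kps",
            "flair_tumor_volume", "flair_total_intensity",
            "t1post_tumor_volume", "t1post_total_intensity",
            "model_prediction",
        ]

    def test_null_predictor_rejection_rate_calibrated(self):
        r = np.random.default_rng(3)
        rejections = 0
        sims = 500
        covs = self._covs(60, seed=3)
        for _ in range(sims):
            y = r.normal(size=60)
            pred = r.normal(size=60)
            p = covariate_adjusted_regression(y, pred, covs)
            rejections += p["model_prediction"] < 0.05
        assert 0.01 <= rejections / sims <= 0.12

    def test_rank_deficiency_names_columns(self):
        covs = self._covs(40, seed=4)
        covs["t1post_tumor_volume"] = covs["flair_tumor_volume"]
        r = np.random.default_rng(4)
        with pytest.raises(ValueError, match="tumor_volume"):
            covariate_adjusted_regression(
                r.normal(size=40), r.normal(size=40), covs
            )


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        g = pd.DataFrame({"v": np.arange(10.0)})
        p = kruskal_wallis_balance(g, g.copy(), ["v"])
        assert p["v"] == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        r = np.random.default_rng(5)
        a = pd.DataFrame({"v": r.normal(0, 1, 50)})
        b = pd.DataFrame({"v": r.normal(3, 1, 50)})
        assert kruskal_wallis_balance(a, b, ["v"])["v"] < 0.001

    def test_constant_variable_flagged_nan(self):
        a = pd.DataFrame({"v": np.ones(5)})
        b = pd.DataFrame({"v": np.ones(5)})
        assert np.isnan(kruskal_wallis_balance(a, b, ["v"])["v"])

    def test_p_in_unit_interval(self):
        r = np.random.default_rng(8)
        for seed in range(10):
            a = pd.DataFrame({"v": r.normal(size=12)})
            b = pd.DataFrame({"v": r.normal(size=15)})
            p = kruskal_wallis_balance(a, b, ["v"])["v"]
            assert 0.0 <= p <= 1.0


class TestCompareAuc:
    def test_identical_scores_p_one(self):
        r = np.random.default_rng(9)
        s = r.normal(size=40)
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert compare_auc_bootstrap(s, s.copy(), labels, n_boot=200, seed=0) == 1.0

    def test_perfect_vs_random_significant(self):
        r = np.random.default_rng(10)
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        perfect = labels + 0.01 * r.normal(size=100)
        random_scores = r.normal(size=100)
        p = compare_auc_bootstrap(perfect, random_scores, labels, n_boot=500, seed=1)
        assert p < 0.01

    def test_deterministic_under_seed(self):
        r = np.random.default_rng(11)
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        a = r.normal(size=60) + labels
        b = r.normal(size=60)
        p1 = compare_auc_bootstrap(a, b, labels, n_boot=300, seed=5)
        p2 = compare_auc_bootstrap(a, b, labels, n_boot=300, seed=5)
        assert p1 == p2

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="100"):
            compare_auc_bootstrap([1, 2], [2, 1], [0, 1], n_boot=10)


def test_report_assembly_and_text():
    r = np.random.default_rng(12)
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    scores = y + 0.5 * r.normal(size=40)
    labels = (scores > 0.5).astype(int)
    rep = evaluate_predictions(scores, labels, y, y + r.normal(size=40), n_boot=200, seed=0)
    assert 0 <= rep.auc <= 1
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
    text = rep.to_text()
    assert "AUC" in text and "sensitivity" in text
    roc = roc_curve_points(scores, y)
    assert roc["fpr"].iloc[-1] == 1.0 and roc["tpr"].iloc[-1] == 1.0
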