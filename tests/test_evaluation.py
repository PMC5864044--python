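"""Evaluation battery: exact binomial GOF, classification, Brier, AUROC, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from tirisk.eam_processing import bin_cohort
from tirisk.evaluation import (
    auroc,
    binomial_gof_test,
    brier_score,
    classify_at_cutpoint,
    clopper_pearson_ci,
    evaluate_cohort,
    gof_by_interval,
    kfold_cv_auroc,
    max_accuracy_cutpoint,
)
from tests.conftest import make_summary


class TestBinomialGof:
    @pytest.mark.parametrize(
        "k, n, p0, expected_2dp",
        [
            # reconstructed interval counts behind the published p-values
            (9, 16, 0.33, 0.06),
            (13, 19, 0.55, 0.26),
        ],
    )
    def test_published_interval_pvalues(self, k, n, p0, expected_2dp):
        assert round(binomial_gof_test(k, n, p0), 2) == expected_2dp

    def test_modal_outcome_gives_one(self):
        assert binomial_gof_test(5, 10, 0.5) == pytest.approx(1.0)

    def test_extreme_outcome_direct_sum(self):
        # symmetric null: both extreme points {0, 10} contribute 2/1024
        assert binomial_gof_test(0, 10, 0.5) == pytest.approx(2 / 1024, abs=1e-12)

    @pytest.mark.parametrize("k, n, p0", [(3, 17, 0.21), (0, 9, 0.4), (12, 12, 0.8)])
    def test_matches_scipy_minlike(self, k, n, p0):
        assert binomial_gof_test(k, n, p0) == pytest.approx(
            binomtest(k, n, p0).pvalue, abs=1e-10
        )

    def test_central_method(self):
        # doubled smaller tail, capped at 1
        from scipy.stats import binom

        k, n, p0 = 3, 20, 0.4
        lower = binom.cdf(k, n, p0)
        assert binomial_gof_test(k, n, p0, method="central") == pytest.approx(
            min(1.0, 2 * lower), abs=1e-12
        )

    def test_two_sided_at_least_one_sided(self):
        from scipy.stats import binom

        for k, n, p0 in [(2, 15, 0.5), (11, 14, 0.3), (7, 20, 0.35)]:
            two = binomial_gof_test(k, n, p0)
            one = min(binom.cdf(k, n, p0), binom.sf(k - 1, n, p0))
            assert two >= one - 1e-12

    @pytest.mark.parametrize(
        "k, n, p0, expected",
        [(0, 5, 0.0, 1.0), (3, 5, 0.0, 0.0), (5, 5, 1.0, 1.0), (4, 5, 1.0, 0.0)],
    )
    def test_degenerate_null(self, k, n, p0, expected):
        assert binomial_gof_test(k, n, p0) == expected


class TestClopperPearson:
    def test_closed_form_at_extremes(self):
        lo, hi = clopper_pearson_ci(20, 20)
        assert lo == pytest.approx(0.025 ** (1 / 20), abs=1e-10)
        assert hi == 1.0
        lo0, hi0 = clopper_pearson_ci(0, 20)
        assert lo0 == 0.0
        assert hi0 == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-10)

    def test_symmetric_at_half(self):
        lo, hi = clopper_pearson_ci(10, 20)
        assert lo < 0.5 < hi
        assert lo + hi == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("k, n", [(3, 11), (7, 30), (0, 4), (14, 14)])
    def test_matches_scipy_exact_interval(self, k, n):
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        lo, hi = clopper_pearson_ci(k, n)
        assert lo == pytest.approx(ci.low, abs=1e-10)
        assert hi == pytest.approx(ci.high, abs=1e-10)

    def test_coverage_simulation(self):
        # 1000 seeded binomial replicates at n=50, p=0.3: exact intervals
        # must cover at >= the nominal rate minus 3 MC standard errors
        rng = np.random.default_rng(2024)
        n, p, reps = 50, 0.3, 1000
        ks = rng.binomial(n, p, size=reps)
        covered = np.array([clopper_pearson_ci(int(k), n) for k in ks])
        rate = float(np.mean((covered[:, 0] <= p) & (p <= covered[:, 1])))
        mc_se = np.sqrt(0.95 * 0.05 / reps)
        assert rate >= 0.95 - 3 * mc_se


class TestClassification:
    def test_perfect_predictor(self):
        report = classify_at_cutpoint([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert report.sensitivity.value == 1.0
        assert report.specificity.value == 1.0
        assert report.accuracy.value == 1.0

    def test_constant_positive_predictor(self):
        report = classify_at_cutpoint([0.6] * 4, [1, 1, 0, 0])
        assert report.sensitivity.value == 1.0
        assert report.specificity.value == 0.0
        assert report.accuracy.value == 0.5

    def test_worked_confusion_matrix(self, worked_classification_set):
        probs, outcomes = worked_classification_set
        report = classify_at_cutpoint(probs, outcomes, cutpoint=0.5)
        assert report.sensitivity.value == pytest.approx(4 / 6)
        assert report.specificity.value == pytest.approx(3 / 4)
        assert report.accuracy.value == pytest.approx(7 / 10)
        assert report.confusion == {"tp": 4, "fp": 1, "tn": 3, "fn": 2}

    def test_cut_boundary_inclusive(self):
        report = classify_at_cutpoint([0.5, 0.49], [1, 0], cutpoint=0.5)
        assert report.accuracy.value == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify_at_cutpoint([0.2, 0.8], [1, 1])

    def test_ci_brackets_point(self, worked_classification_set):
        probs, outcomes = worked_classification_set
        report = classify_at_cutpoint(probs, outcomes)
        for est in (report.sensitivity, report.specificity, report.accuracy):
            assert est.lower <= est.value <= est.upper


class TestBrier:
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_constant_half_is_noninformative_bound(self, outcomes):
        assert brier_score([0.5] * len(outcomes), outcomes) == pytest.approx(0.25)

    def test_perfect_predictor(self):
        assert brier_score([1.0, 0.0], [1, 0]) == 0.0

    def test_arithmetic(self):
        assert brier_score([0.8, 0.2], [1, 0]) == pytest.approx(0.04)


class TestAuroc:
    def test_perfect_separation(self):
        area, _ = auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert area == 1.0

    def test_all_ties(self):
        area, _ = auroc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert area == 0.5

    def test_pair_enumeration_example(self):
        # pairs: 0.9>0.8, 0.9>0.1, 0.7<0.8, 0.7>0.1 -> 3 of 4 concordant
        area, _ = auroc([0.9, 0.7, 0.8, 0.1], [1, 1, 0, 0])
        assert area == pytest.approx(0.75)

    def test_equals_brute_force_pair_counting(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 200))
            scores = rng.random(n).round(2)  # rounding forces ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            pos, neg = scores[y == 1], scores[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auroc(scores, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(300)
        y = (scores + rng.normal(0, 0.3, 300) > 0.5).astype(int)
        assert auroc(scores, y)[0] == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [0, 0])

    def test_ci_brackets_area(self, rng):
        scores = rng.random(80)
        y = (scores > 0.4).astype(int)
        area, (lo, hi) = auroc(scores, y)
        assert 0.0 <= lo <= area <= hi <= 1.0


class TestKfoldCv:
    def test_perfect_separation(self):
        scores = np.concatenate([np.linspace(0.6, 1, 50), np.linspace(0, 0.4, 50)])
        y = np.array([1] * 50 + [0] * 50)
        mean, _, skipped = kfold_cv_auroc(scores, y, k=10, seed=1)
        assert mean == 1.0

    def test_uninformative_scores(self, rng):
        scores = rng.random(2000)
        y = rng.integers(0, 2, size=2000)
        mean, _, _ = kfold_cv_auroc(scores, y, k=10, seed=3)
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_deterministic_given_seed(self, rng):
        scores = rng.random(100)
        y = rng.integers(0, 2, size=100)
        assert kfold_cv_auroc(scores, y, seed=7) == kfold_cv_auroc(scores, y, seed=7)

    def test_too_many_single_class_folds_rejected(self):
        scores = np.linspace(0, 1, 20)
        y = np.array([0] * 19 + [1])
        with pytest.raises(ValueError):
            kfold_cv_auroc(scores, y, k=10, seed=0)


class TestMaxAccuracyCutpoint:
    def test_perfect_separation(self):
        cut, acc = max_accuracy_cutpoint([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert acc == 1.0
        assert 0.2 < cut <= 0.8

    def test_worked_set_exhaustive(self, worked_classification_set):
        probs, outcomes = worked_classification_set
        cut, acc = max_accuracy_cutpoint(probs, outcomes)
        # brute force over all cuts at observed values
        best = max(
            np.mean((np.array(probs) >= c) == np.array(outcomes))
            for c in set(probs)
        )
        assert acc == pytest.approx(best)

    def test_single_candidate(self):
        cut, _ = max_accuracy_cutpoint([0.4, 0.4], [1, 0])
        assert cut == 0.4

    def test_low_direction_for_adherence_scale(self):
        # low adherence predicts interruption
        adherence = [0.5, 0.6, 0.9, 0.95]
        outcomes = [1, 1, 0, 0]
        cut, acc = max_accuracy_cutpoint(adherence, outcomes, positive_when="low")
        assert acc == 1.0
        assert 0.6 < cut <= 0.9


class TestEvaluateCohort:
    def test_report_structure_and_consistency(self):
        rng = np.random.default_rng(11)
        summaries = []
        for i in range(120):
            q = float(rng.uniform(0.45, 0.96))
            prob_true = 1.0 if q < 0.7 else 0.15
            summaries.append(
                make_summary(f"p{i}", q, bool(rng.random() < prob_true))
            )
        binned = bin_cohort(summaries)
        report = evaluate_cohort(summaries, binned, r=3, n=90, seed=5)
        assert set(report) >= {
            "gof", "classification", "brier", "auroc", "cv_auroc", "max_accuracy",
        }
        assert 0.0 <= report["brier"] <= 1.0
        assert 0.0 <= report["auroc"]["value"] <= 1.0
        assert sum(g["n"] for g in report["gof"]) == binned.total
        for g in report["gof"]:
            assert 0.0 <= g["p_value"] <= 1.0

    def test_gof_skips_empty_intervals(self):
        summaries = [make_summary("a", 0.45, True), make_summary("b", 0.46, False)]
        binned = bin_cohort(summaries)
        results = gof_by_interval(binned, 3, 90)
        assert len(results) == 1
        assert results[0].n == 2
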