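"""Confusion metrics, MCC, ROC/Youden, cross-validation, Wilcoxon test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voiceicpr.data import FeatureTable
from voiceicpr.evaluate import (
    ClassifierSpec,
    ConfusionMatrix,
    build_cv_plan,
    confusion_metrics,
    evaluation_summary,
    k_fold_cv,
    mcc,
    roc_curve,
    wilcoxon_compare,
    youden_cutoff,
)
from conftest import DESIGNED_FEATURES


class TestConfusionMetrics:
    def test_svm_icpr_operating_point(self):
        # 147 patients / 48 controls; sens 0.9252 and spec 0.8542 imply
        # TP=136, TN=41
        m = confusion_metrics(ConfusionMatrix(tp=136, fn=11, tn=41, fp=7))
        assert m.accuracy == pytest.approx(0.9077, abs=5e-5)
        assert m.sensitivity == pytest.approx(0.9252, abs=5e-5)
        assert m.specificity == pytest.approx(0.8542, abs=5e-5)

    def test_perfect_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fn=0, tn=5, fp=0))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_empty_positive_class_flagged(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=2))
        assert math.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    def test_accuracy_identity(self, tp, fp, tn, fn):
        # accuracy = (P*sens + N*spec) / (P+N) whenever all terms defined
        if tp + fn == 0 or tn + fp == 0:
            return
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        m = confusion_metrics(cm)
        P, N = tp + fn, tn + fp
        assert m.accuracy == pytest.approx(
            (P * m.sensitivity + N * m.specificity) / (P + N), rel=1e-12
        )


class TestMcc:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(tp=136, fn=11, tn=41, fp=7), 0.7592),   # SVM/overlap
            (ConfusionMatrix(tp=141, fn=6, tn=33, fp=15), 0.6964),   # bagging/MKLD
            (ConfusionMatrix(tp=134, fn=13, tn=28, fp=20), 0.5232),  # GLRA/MKLD
            (ConfusionMatrix(tp=137, fn=10, tn=28, fp=20), 0.5604),  # GLRA/overlap
            (ConfusionMatrix(tp=133, fn=14, tn=40, fp=8), 0.7105),   # SVM/MKLD
        ],
    )
    def test_reported_operating_points(self, cm, expected):
        assert mcc(cm) == pytest.approx(expected, abs=5e-5)

    def test_perfect_agreement_is_one(self):
        assert mcc(ConfusionMatrix(tp=147, fn=0, tn=48, fp=0)) == pytest.approx(1.0)

    def test_total_disagreement_is_minus_one(self):
        assert mcc(ConfusionMatrix(tp=0, fn=10, tn=0, fp=5)) == pytest.approx(-1.0)

    def test_degenerate_factor_convention_zero(self):
        assert mcc(ConfusionMatrix(tp=0, fn=0, tn=3, fp=2)) == 0.0

    def test_zero_for_truth_independent_predictions(self):
        rng = np.random.default_rng(123)
        truth = np.where(rng.random(20000) < 0.7, 1, -1)
        pred = np.where(rng.random(20000) < 0.4, 1, -1)
        cm = ConfusionMatrix.from_predictions(truth, pred)
        assert abs(mcc(cm)) < 0.02


class TestRocCurve:
    def test_perfect_ranking_auc_one(self):
        labels = np.array([1, 1, 1, -1, -1])
        assert roc_curve(labels.astype(float), labels).auc == pytest.approx(1.0)

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(7)
        labels = np.where(rng.random(10000) < 0.5, 1, -1)
        scores = rng.standard_normal(10000)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_normalised_mann_whitney(self):
        # brute force over all positive-negative pairs, ties counted half
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 5, 30).astype(float)
        labels = np.where(rng.random(30) < 0.5, 1, -1)
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == -1]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        expected = wins / (len(pos) * len(neg))
        assert roc_curve(scores, labels).auc == pytest.approx(expected, rel=1e-12)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal(50)
        labels = np.where(rng.random(50) < 0.6, 1, -1)
        c = roc_curve(scores, labels)
        assert (np.diff(c.tpr) >= 0).all() and (np.diff(c.fpr) >= 0).all()
        assert c.tpr[0] == 0 and c.fpr[0] == 0
        assert c.tpr[-1] == 1 and c.fpr[-1] == 1

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(100)
        labels = np.where(rng.random(100) < 0.6, 1, -1)
        base = roc_curve(scores, labels).auc
        for f in (np.exp, np.tanh, lambda s: 3 * s + 7):
            assert roc_curve(f(scores), labels).auc == pytest.approx(base, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))


class TestYoudenCutoff:
    def test_perfect_classifier_index_one(self):
        labels = np.array([1, 1, -1, -1])
        _, j = youden_cutoff(roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), labels))
        assert j == pytest.approx(1.0)

    def test_reported_bagging_operating_point_arithmetic(self):
        # sens 0.9796 + spec 0.6875 - 1 = 0.6671
        assert 0.9796 + 0.6875 - 1 == pytest.approx(0.6671, abs=1e-12)

    def test_uninformative_scores_index_near_zero(self):
        rng = np.random.default_rng(4)
        labels = np.where(rng.random(5000) < 0.5, 1, -1)
        _, j = youden_cutoff(roc_curve(rng.standard_normal(5000), labels))
        assert j < 0.08

    def test_cutoff_maximises_index(self):
        rng = np.random.default_rng(9)
        labels = np.where(rng.random(200) < 0.6, 1, -1)
        scores = rng.standard_normal(200) + 0.8 * labels
        c = roc_curve(scores, labels)
        thr, j = youden_cutoff(c)
        pred = np.where(scores >= thr, 1, -1)
        cm = ConfusionMatrix.from_predictions(labels, pred)
        m = confusion_metrics(cm)
        assert m.sensitivity + m.specificity - 1 == pytest.approx(j, abs=1e-12)
        assert j == pytest.approx(max(c.tpr - c.fpr), abs=1e-12)


def _cohort_195():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((195, 2))
    labels = np.array([-1] * 48 + [1] * 147)
    X[labels == 1] += 1.5
    subjects = [f"s{i % 31}" for i in range(195)]
    return FeatureTable(["f0", "f1"], X, labels, subjects)


class TestCrossValidation:
    def test_195_rows_five_folds_of_39(self):
        t = _cohort_195()
        plan = build_cv_plan(t, n_folds=5, seed=1)
        sizes = np.bincount(plan.fold_assignments)
        assert sizes.tolist() == [39] * 5

    def test_stratification_preserves_class_ratio(self):
        t = _cohort_195()
        plan = build_cv_plan(t, n_folds=5, seed=1, stratified=True)
        for k in range(5):
            in_fold = t.labels[plan.fold_assignments == k]
            assert abs((in_fold == 1).mean() - 147 / 195) < 0.05

    def test_subject_aware_folds_do_not_split_subjects(self):
        t = _cohort_195()
        plan = build_cv_plan(t, n_folds=5, seed=1, subject_aware=True)
        for subj in set(t.subject_ids):
            rows = [i for i, s in enumerate(t.subject_ids) if s == subj]
            assert len(set(plan.fold_assignments[rows])) == 1

    def test_always_positive_classifier_pooled_rates(self):
        t = _cohort_195()
        plan = build_cv_plan(t, seed=0)

        class AlwaysPositive(ClassifierSpec):
            def __init__(self):
                super().__init__("constant")

            def fit_and_score(self, train, test, features, seed):
                return np.ones(test.n_rows), np.ones(test.n_rows, dtype=int)

        res = k_fold_cv(t, plan, AlwaysPositive(), ["f0"])
        m = confusion_metrics(res.pooled_confusion)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_same_seed_identical_pooled_confusion(self):
        t = _cohort_195()
        p1 = build_cv_plan(t, seed=5)
        p2 = build_cv_plan(t, seed=5)
        r1 = k_fold_cv(t, p1, ClassifierSpec("bagging", {"n_trees": 10}), ["f0", "f1"])
        r2 = k_fold_cv(t, p2, ClassifierSpec("bagging", {"n_trees": 10}), ["f0", "f1"])
        assert r1.pooled_confusion == r2.pooled_confusion

    def test_missing_class_in_training_fold_named(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 1))
        t = FeatureTable(["f0"], X, [1] * 9 + [-1], [f"s{i}" for i in range(10)])
        plan = build_cv_plan(t, n_folds=2, seed=0, stratified=False)
        # put the single control alone in fold 0's training complement
        plan.fold_assignments[:] = [0] * 5 + [1] * 5
        plan.fold_assignments[9] = 0  # control held out in fold 0 -> fold 1 trains without it
        plan.fold_assignments[4] = 1
        with pytest.raises(ValueError, match="fold"):
            k_fold_cv(t, plan, ClassifierSpec("glra"), ["f0"])

    def test_summary_fields_complete(self, informative_cohort):
        plan = build_cv_plan(informative_cohort, seed=2)
        res = k_fold_cv(informative_cohort, plan, ClassifierSpec("svm"),
                        DESIGNED_FEATURES)
        s = evaluation_summary(res)
        assert set(s) >= {"confusion", "accuracy", "sensitivity", "specificity",
                          "mcc", "auc", "youden_threshold"}
        assert 0.5 < s["auc"] <= 1.0


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        a = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero"):
            stat, p = wilcoxon_compare(a, a)
        assert p == 1.0

    def test_exact_small_sample_matches_enumeration(self):
        # brute-force null: all 2^n sign assignments of the rank sums
        rng = np.random.default_rng(42)
        d = rng.standard_normal(8)
        d = np.where(d == 0, 0.1, d)
        a = np.zeros(8)
        stat, p = wilcoxon_compare(a + d, a)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        n = len(d)
        dist = []
        for signs in itertools.product([0, 1], repeat=n):
            dist.append(sum(r for r, s in zip(ranks, signs) if s))
        dist = np.array(dist)
        w_min = min(w_obs, n * (n + 1) / 2 - w_obs)
        p_exact = min(
            1.0,
            2 * min(
                (dist <= w_min).mean(),
                (dist >= w_min).mean(),
            ),
        )
        # scipy reports min(W+, W-) as the statistic in two-sided mode
        assert stat == w_min
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_uniform_dominance_small_p(self):
        a = np.arange(20.0) + 1.0
        b = np.arange(20.0)
        _, p = wilcoxon_compare(a, b)
        assert p < 1e-3

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wilcoxon_compare(np.ones(3), np.zeros(3))
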