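"""Classifier evaluation: confusion metrics, ROC, cross-validation, tests.

Conventions: the patient class carries label +1 (so sensitivity is the
patient detection rate, specificity the control detection rate), metrics
follow

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    MCC         = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC defined as 0 when any denominator factor vanishes. Cross-
validation pools held-out predictions over folds before computing a single
confusion matrix and ROC curve, which reports counts rather than averaged
per-fold rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold, KFold

from .classify import (
    bagging_error_curve,
    fit_bagging,
    fit_glra,
    fit_svm_rbf,
    predict_glra,
)
from .data import FeatureTable

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "RocCurve",
    "CvPlan",
    "CvResult",
    "ClassifierSpec",
    "confusion_metrics",
    "mcc",
    "roc_curve",
    "youden_cutoff",
    "build_cv_plan",
    "k_fold_cv",
    "wilcoxon_compare",
    "evaluation_summary",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_predictions(
        cls, truth: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionMatrix":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        return cls(
            tp=int(np.sum((truth == 1) & (predicted == 1))),
            fp=int(np.sum((truth == -1) & (predicted == 1))),
            tn=int(np.sum((truth == -1) & (predicted == -1))),
            fn=int(np.sum((truth == 1) & (predicted == -1))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy / sensitivity / specificity; NaN where a rate is undefined."""

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


def confusion_metrics(cm: ConfusionMatrix) -> Metrics:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn > 0:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    if cm.tn + cm.fp > 0:
        specificity = cm.tn / (cm.fp + cm.tn)
    else:
        specificity = float("nan")
        undefined.append("specificity")
    return Metrics(accuracy, sensitivity, specificity, tuple(undefined))


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Threshold sweep over unique scores (ties grouped), trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    present = set(np.unique(labels))
    if present != {-1, 1}:
        raise ValueError(f"need both classes among labels, found {sorted(present)}")
    fpr, tpr, thr = skmetrics.roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def youden_cutoff(curve: RocCurve) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    Ties go to the operating point with higher specificity (lower FPR).
    The first sweep point (the above-maximum sentinel threshold) is
    excluded.
    """
    j = curve.tpr - curve.fpr
    # candidate order: maximise J, then minimise fpr, then larger threshold
    order = sorted(
        range(1, len(j)),
        key=lambda i: (-j[i], curve.fpr[i], -curve.thresholds[i]),
    )
    best = order[0]
    return float(curve.thresholds[best]), float(j[best])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    """A fold assignment for k-fold cross-validation.

    ``stratified`` preserves class proportions per fold; ``subject_aware``
    keeps all recordings of one subject in a single fold (guarding against
    leakage when subjects contribute several recordings, at the cost of
    slightly uneven folds).
    """

    n_folds: int
    fold_assignments: np.ndarray
    seed: int
    stratified: bool
    subject_aware: bool


def build_cv_plan(
    table: FeatureTable,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
    subject_aware: bool = False,
) -> CvPlan:
    """Assign each row to one of ``n_folds`` folds, reproducibly from seed."""
    n = table.n_rows
    assign = np.full(n, -1, dtype=int)
    if subject_aware:
        # greedy balance: shuffle subjects, place each whole subject into
        # the currently smallest fold
        rng = np.random.default_rng(seed)
        subjects = {}
        for i, s in enumerate(table.subject_ids):
            subjects.setdefault(s, []).append(i)
        order = sorted(subjects)
        rng.shuffle(order)
        sizes = np.zeros(n_folds, dtype=int)
        for s in sorted(order, key=lambda s: -len(subjects[s])):
            k = int(np.argmin(sizes))
            assign[subjects[s]] = k
            sizes[k] += len(subjects[s])
    else:
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
        y = table.labels
        for k, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
            assign[test_idx] = k
    return CvPlan(n_folds, assign, seed, stratified, subject_aware)


@dataclass
class ClassifierSpec:
    """Which classifier to run in CV, and with which hyperparameters.

    kind: 'glra', 'svm' or 'bagging'. params are forwarded to the fit
    function (e.g. spread/regularization for svm, n_trees for bagging).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def fit_and_score(
        self, train: FeatureTable, test: FeatureTable, features: list[str], seed: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fit on ``train``, return (scores, labels) for ``test`` rows."""
        if self.kind == "glra":
            model = fit_glra(train, features, **self.params)
            prob, labels = predict_glra(model, test)
            return prob, labels
        if self.kind == "svm":
            model = fit_svm_rbf(train, features, **self.params)
            return model.decision_values(test), model.predict(test)
        if self.kind == "bagging":
            model = fit_bagging(train, features, seed=seed, **self.params)
            return model.positive_vote_fraction(test), model.predict(test)
        raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class CvResult:
    pooled_confusion: ConfusionMatrix
    pooled_scores: np.ndarray
    pooled_truth: np.ndarray
    per_fold_metrics: list[Metrics]
    correct_indicator: np.ndarray
    plan: CvPlan


def k_fold_cv(
    table: FeatureTable,
    plan: CvPlan,
    classifier: ClassifierSpec,
    features: list[str],
) -> CvResult:
    """Train/test each fold once; pool held-out predictions across folds.

    The pooled confusion matrix and score vector cover every row exactly
    once. Reproducible from (plan, classifier params): per-fold bagging
    seeds derive from the plan seed.
    """
    n = table.n_rows
    if sorted(np.unique(plan.fold_assignments)) != list(range(plan.n_folds)):
        raise ValueError("plan does not partition rows into the stated folds")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    per_fold = []
    for k in range(plan.n_folds):
        test_mask = plan.fold_assignments == k
        train = table.subset_rows(~test_mask)
        test = table.subset_rows(test_mask)
        if not train.both_classes_present():
            raise ValueError(f"training data for fold {k} lacks one class")
        fold_seed = (plan.seed * 1000003 + k) % (2**31 - 1)
        s, p = classifier.fit_and_score(train, test, features, seed=fold_seed)
        scores[test_mask] = s
        preds[test_mask] = p
        per_fold.append(
            confusion_metrics(ConfusionMatrix.from_predictions(test.labels, p))
        )
    pooled = ConfusionMatrix.from_predictions(table.labels, preds)
    return CvResult(
        pooled_confusion=pooled,
        pooled_scores=scores,
        pooled_truth=table.labels.copy(),
        per_fold_metrics=per_fold,
        correct_indicator=(preds == table.labels).astype(int),
        plan=plan,
    )


def wilcoxon_compare(
    per_unit_scores_a: np.ndarray, per_unit_scores_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-unit scores.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 informative pairs when ranks are untied, otherwise the normal
    approximation with tie correction. All-zero differences give p = 1
    with a warning.
    """
    a = np.asarray(per_unit_scores_a, dtype=float)
    b = np.asarray(per_unit_scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired units")
    d = a - b
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; test is uninformative",
                      stacklevel=2)
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def evaluation_summary(result: CvResult) -> dict:
    """JSON-ready summary: confusion counts, rates, MCC, AUC, Youden cutoff."""
    m = confusion_metrics(result.pooled_confusion)
    curve = roc_curve(result.pooled_scores, result.pooled_truth)
    threshold, j = youden_cutoff(curve)
    cm = result.pooled_confusion
    return {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "mcc": mcc(cm),
        "auc": curve.auc,
        "youden_threshold": threshold,
        "youden_index": j,
    }
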