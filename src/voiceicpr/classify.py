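"""Three classifiers for two-class voice-pattern discrimination.

* Generalized logistic regression (GLRA): logit link
  ln(P₊/P₋) = β₀ + x·β, fitted by iteratively reweighted least squares
  (maximum likelihood) with step halving, so the log-likelihood never
  decreases across iterations. Complete separation is detected and
  reported via ``converged=False`` rather than raised; the diverging fit
  still ranks cases correctly.

* RBF-kernel maximum-margin classifier: the standard soft-margin dual with
  Gaussian kernel K(u, v) = exp(−‖u−v‖² / (2σ²)), default spread σ = 1.
  The quadratic program is solved by scikit-learn's SMO implementation;
  the kernel parameterisation and the sign decision rule are fixed here.

* Bagging: 50 CART-style decision trees (Gini impurity, grown to purity,
  all features considered at every split — bootstrap aggregation, not a
  random forest), each fitted to a bootstrap resample of the full training
  size; labels by majority vote with ties broken toward the control (−1)
  class, and the positive-vote fraction retained as a ROC score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import FeatureTable

__all__ = [
    "GlraModel",
    "KernelMarginModel",
    "BaggedEnsemble",
    "fit_glra",
    "predict_glra",
    "fit_svm_rbf",
    "fit_bagging",
    "bagging_error_curve",
]

_COEF_DIVERGENCE_LIMIT = 1e8


@dataclass
class GlraModel:
    """Fitted logistic model: β = [β₀, β₁, …] over ``feature_order``."""

    coefficients: np.ndarray
    feature_order: list[str]
    converged: bool
    iterations: int
    log_likelihood: float
    standard_errors: np.ndarray | None = None
    standardize: bool = False
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    diagnostics: str = ""

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "feature_order": list(self.feature_order),
            "converged": self.converged,
            "iterations": self.iterations,
            "log_likelihood": self.log_likelihood,
        }


def _design(model_or_features, table: FeatureTable) -> np.ndarray:
    features = (
        model_or_features.feature_order
        if isinstance(model_or_features, GlraModel)
        else model_or_features
    )
    X = table.matrix(features)
    if isinstance(model_or_features, GlraModel) and model_or_features.standardize:
        X = (X - model_or_features.feature_means) / model_or_features.feature_sds
    return np.column_stack([np.ones(len(X)), X])


def _log_likelihood(eta: np.ndarray, y01: np.ndarray) -> float:
    # numerically stable: log(sigma(eta)) = -log1p(exp(-eta))
    return float(np.sum(y01 * eta - np.logaddexp(0.0, eta)))


def fit_glra(
    table: FeatureTable,
    features: list[str],
    standardize: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
) -> GlraModel:
    """Maximum-likelihood logistic fit by IRLS with step halving.

    Iterates until the relative change in log-likelihood drops below
    ``tol`` or ``max_iter`` Newton steps. With completely separated
    classes the ML estimate diverges; this is flagged via
    ``converged=False`` and a diagnostic, and the returned coefficients
    (from the last stable step) remain usable for ranking.
    """
    if not table.both_classes_present():
        raise ValueError("both classes required to fit a logistic model")
    X = table.matrix(features)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if standardize:
        if (sds == 0).any():
            raise ValueError("cannot standardize a zero-variance feature")
        X = (X - means) / sds
    Xd = np.column_stack([np.ones(len(X)), X])
    y01 = (table.labels == 1).astype(float)

    beta = np.zeros(Xd.shape[1])
    ll = _log_likelihood(Xd @ beta, y01)
    converged = False
    diagnostics = ""
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        # Newton step on the penalised score; ridge=0 is the pure ML fit
        H = Xd.T @ (Xd * w[:, None]) + ridge * np.eye(Xd.shape[1])
        g = Xd.T @ (y01 - p) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H = H + 1e-10 * np.trace(H) / H.shape[0] * np.eye(H.shape[0])
            step = np.linalg.solve(H, g)
        # step halving keeps the log-likelihood monotone
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _log_likelihood(Xd @ candidate, y01)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_prev, ll = ll, _log_likelihood(Xd @ beta, y01)
        if np.abs(beta).max() > _COEF_DIVERGENCE_LIMIT:
            diagnostics = "coefficients diverging: classes may be completely separated"
            break
        if abs(ll - ll_prev) <= tol * (abs(ll_prev) + tol):
            converged = True
            break

    p = expit(Xd @ beta)
    w = p * (1.0 - p)
    # complete separation: every fitted probability pinned at 0/1 with all
    # cases classified correctly; the ML estimate diverges, so the stopping
    # rule above may have fired on a vanishing likelihood change
    separated = bool(w.max() < 1e-6 and ((p >= 0.5) == (y01 == 1.0)).all())
    if separated:
        converged = False
        diagnostics = "coefficients diverging: classes are completely separated"
    elif not converged and not diagnostics:
        if np.abs(beta).max() > 1e4:
            diagnostics = "coefficients diverging: classes may be completely separated"
        else:
            diagnostics = f"no convergence within {n_iter} iterations"

    info = Xd.T @ (Xd * w[:, None])
    try:
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = None
    return GlraModel(
        coefficients=beta,
        feature_order=list(features),
        converged=converged,
        iterations=n_iter,
        log_likelihood=ll,
        standard_errors=se,
        standardize=standardize,
        feature_means=means if standardize else None,
        feature_sds=sds if standardize else None,
        diagnostics=diagnostics,
    )


def predict_glra(
    model: GlraModel, table: FeatureTable, cutoff: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (probability of the +1 class, predicted label).

    Label is +1 iff the probability reaches ``cutoff``. Uses the
    numerically stable logistic, so large linear predictors saturate at
    0/1 without overflow.
    """
    missing = [f for f in model.feature_order if f not in table.feature_names]
    if missing:
        raise KeyError(f"table lacks model features: {missing}")
    eta = _design(model, table) @ model.coefficients
    prob = expit(eta)
    labels = np.where(prob >= cutoff, 1, -1)
    return prob, labels


@dataclass
class KernelMarginModel:
    """Fitted soft-margin RBF classifier (thin wrapper over the SMO dual)."""

    support_points: np.ndarray
    dual_weights: np.ndarray
    kernel_spread: float
    bias: float
    regularization: float
    feature_order: list[str]
    _svc: SVC = field(repr=False, default=None)

    def decision_values(self, table: FeatureTable) -> np.ndarray:
        return self._svc.decision_function(table.matrix(self.feature_order))

    def predict(self, table: FeatureTable) -> np.ndarray:
        d = self.decision_values(table)
        return np.where(d >= 0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "kernel_spread": self.kernel_spread,
            "regularization": self.regularization,
            "n_support": int(len(self.support_points)),
            "bias": self.bias,
            "feature_order": list(self.feature_order),
        }


def fit_svm_rbf(
    table: FeatureTable,
    features: list[str],
    spread: float = 1.0,
    regularization: float = 1.0,
) -> KernelMarginModel:
    """Soft-margin maximum-margin fit with Gaussian kernel.

    ``spread`` is the kernel width σ in K(u,v) = exp(−‖u−v‖²/(2σ²)), i.e.
    scikit-learn's ``gamma = 1/(2σ²)``. ``regularization`` is the box
    constraint C of the dual.
    """
    if spread <= 0:
        raise ValueError(f"kernel spread must be positive, got {spread}")
    if regularization <= 0:
        raise ValueError(f"regularization C must be positive, got {regularization}")
    if not table.both_classes_present():
        raise ValueError("both classes required to fit a margin classifier")
    X = table.matrix(features)
    svc = SVC(kernel="rbf", gamma=1.0 / (2.0 * spread**2), C=regularization)
    svc.fit(X, table.labels)
    return KernelMarginModel(
        support_points=svc.support_vectors_,
        dual_weights=svc.dual_coef_.ravel(),
        kernel_spread=float(spread),
        bias=float(svc.intercept_[0]),
        regularization=float(regularization),
        feature_order=list(features),
        _svc=svc,
    )


@dataclass
class BaggedEnsemble:
    """Bootstrap-aggregated decision trees with majority-vote prediction."""

    trees: list[DecisionTreeClassifier]
    feature_order: list[str]
    bootstrap_seed: int
    n_trees: int

    def _votes(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        """Count of +1 votes per row over the first ``n_trees`` trees."""
        use = self.trees if n_trees is None else self.trees[:n_trees]
        votes = np.zeros(len(X), dtype=int)
        for tree in use:
            votes += (tree.predict(X) == 1).astype(int)
        return votes

    def positive_vote_fraction(self, table: FeatureTable) -> np.ndarray:
        X = table.matrix(self.feature_order)
        return self._votes(X) / len(self.trees)

    def predict(self, table: FeatureTable, n_trees: int | None = None) -> np.ndarray:
        """Majority-vote labels; exact ties go to the control (−1) class."""
        X = table.matrix(self.feature_order)
        t = len(self.trees) if n_trees is None else n_trees
        votes = self._votes(X, t)
        return np.where(votes * 2 > t, 1, -1)

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "bootstrap_seed": self.bootstrap_seed,
            "feature_order": list(self.feature_order),
        }


def fit_bagging(
    table: FeatureTable,
    features: list[str],
    n_trees: int = 50,
    seed: int = 0,
) -> BaggedEnsemble:
    """Fit a bagged ensemble of CART trees.

    Each tree sees a bootstrap resample (with replacement) of the full
    training size. Deterministic for a fixed seed: both the resamples and
    the trees' internal tie-breaking derive from it.
    """
    if n_trees < 1:
        raise ValueError("need at least one tree")
    if table.n_rows == 0:
        raise ValueError("cannot fit on an empty table")
    X = table.matrix(features)
    y = table.labels
    rng = np.random.default_rng(seed)
    n = len(X)
    trees = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            criterion="gini",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return BaggedEnsemble(
        trees=trees,
        feature_order=list(features),
        bootstrap_seed=seed,
        n_trees=n_trees,
    )


def bagging_error_curve(ensemble: BaggedEnsemble, table: FeatureTable) -> np.ndarray:
    """Misclassification rate of the first-t-trees majority vote, t = 1..T.

    Evaluated by resubstitution on ``table``; on held-out data the same
    sweep gives a generalization-error curve.
    """
    X = table.matrix(ensemble.feature_order)
    y = table.labels
    per_tree = np.stack([(tree.predict(X) == 1).astype(int) for tree in ensemble.trees])
    cum_votes = np.cumsum(per_tree, axis=0)
    errors = np.empty(len(ensemble.trees))
    for t in range(1, len(ensemble.trees) + 1):
        pred = np.where(cum_votes[t - 1] * 2 > t, 1, -1)
        errors[t - 1] = np.mean(pred != y)
    return errors
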