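"""Collapse correlated feature groups to single Fisher-discriminant scores.

Jitter-type perturbation measures, shimmer-type measures, and the DFA/PPE
nonlinear pair are nearly collinear (pairwise Pearson r typically above
0.9), so scoring them separately inflates the candidate list with
redundant features. Each strongly correlated group (|r| > 0.8) is
projected onto the two-class Fisher discriminant direction
w ∝ S_W⁻¹(μ₊ − μ₋), yielding one scalar feature per group; by convention
these are named MDVP-LDA (jitter block + NHR), Shimmer-LDA and
Nonlinear-LDA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable

__all__ = [
    "CorrelationGroups",
    "LdaProjection",
    "pearson_matrix",
    "find_groups",
    "fisher_lda",
    "fisher_criterion",
    "apply_projection",
    "append_group_projections",
    "PREDEFINED_GROUPS",
    "REFERENCE_LDA_COEFFICIENTS",
    "REFERENCE_GLRA_COEFFICIENTS",
    "TABLE_CANDIDATES",
]

CORRELATION_THRESHOLD_DEFAULT = 0.8

#: Ridge added to S_W, relative to trace(S_W)/p; the shimmer block contains
#: an exactly collinear pair (Shimmer:APQ3 and Shimmer:DDA), so the raw
#: within-class scatter of that group is singular.
RIDGE_REL = 1e-8

#: The three canonical correlated groups of the 22-feature voice panel.
PREDEFINED_GROUPS: dict[str, list[str]] = {
    "MDVP-LDA": [
        "MDVP:Jitter(%)",
        "MDVP:Jitter(Abs)",
        "MDVP:RAP",
        "MDVP:PPQ",
        "Jitter:DDP",
        "NHR",
    ],
    "Shimmer-LDA": [
        "MDVP:Shimmer",
        "MDVP:Shimmer(dB)",
        "Shimmer:APQ3",
        "Shimmer:APQ5",
        "MDVP:APQ11",
        "Shimmer:DDA",
    ],
    "Nonlinear-LDA": ["DFA", "PPE"],
}

#: Reference combination coefficients for the three groups on the UCI
#: Parkinsons panel. The Fisher direction is defined only up to a positive
#: scalar, and ICPR/MKLD are invariant to that scalar (the bandwidth scales
#: with the data); these fixed vectors make the combined columns exactly
#: reproducible.
REFERENCE_LDA_COEFFICIENTS: dict[str, list[float]] = {
    "MDVP-LDA": [0.0062, 4.4e-05, 0.0033, 0.0034, 0.0099, 0.0248],
    "Shimmer-LDA": [0.0297, 0.2823, 0.0157, 0.0179, 0.0241, 0.047],
    "Nonlinear-LDA": [-5.6844, 0.2066],
}

#: Reference logistic-regression coefficients [intercept, MDVP:F0, Spread1,
#: MDVP-LDA, Shimmer-LDA, Nonlinear-LDA] for the same panel, kept as a
#: fixture for comparison; a fresh maximum-likelihood fit is not expected
#: to reproduce them exactly.
REFERENCE_GLRA_COEFFICIENTS: list[float] = [1.362, -0.003, 7.856, -0.021, 0.005, 25.71]

#: The 11 candidate features scored after collapsing the three groups.
TABLE_CANDIDATES: list[str] = [
    "MDVP:F0",
    "MDVP:Fhi",
    "MDVP:Flo",
    "HNR",
    "RPDE",
    "D2",
    "Spread1",
    "Spread2",
    "MDVP-LDA",
    "Shimmer-LDA",
    "Nonlinear-LDA",
]


@dataclass
class CorrelationGroups:
    """A Pearson correlation matrix plus the groups extracted from it."""

    correlation_matrix: pd.DataFrame
    groups: list[list[str]] = field(default_factory=list)
    threshold: float = CORRELATION_THRESHOLD_DEFAULT

    def to_csv(self, path) -> None:
        self.correlation_matrix.to_csv(path, float_format="%.4f")


@dataclass
class LdaProjection:
    """A correlated group, its combination coefficients, and the scalar feature."""

    group_name: str
    member_features: list[str]
    coefficients: np.ndarray
    projected_values: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.member_features),):
            raise ValueError("one coefficient per member feature required")


def pearson_matrix(table: FeatureTable, features: list[str]) -> CorrelationGroups:
    """Pairwise Pearson correlations of the named features."""
    if table.n_rows < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    X = table.matrix(features)
    sd = X.std(axis=0, ddof=1)
    dead = [f for f, s in zip(features, sd) if s == 0.0]
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return CorrelationGroups(
        correlation_matrix=pd.DataFrame(corr, index=features, columns=features)
    )


def find_groups(
    matrix: CorrelationGroups,
    threshold: float = CORRELATION_THRESHOLD_DEFAULT,
    mode: str = "connected_components",
) -> CorrelationGroups:
    """Extract strongly correlated feature groups.

    ``connected_components`` links features with |r| strictly above
    ``threshold`` and returns the connected components of size >= 2, each
    ordered as in the matrix. ``predefined`` returns the three canonical
    voice-panel groups (jitter block + NHR, shimmer block, DFA + PPE)
    regardless of the matrix.
    """
    if mode == "predefined":
        groups = [list(m) for m in PREDEFINED_GROUPS.values()]
    elif mode == "connected_components":
        names = list(matrix.correlation_matrix.columns)
        corr = matrix.correlation_matrix.to_numpy()
        parent = list(range(len(names)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > threshold:
                    parent[find(i)] = find(j)
        comps: dict[int, list[str]] = {}
        for i, name in enumerate(names):
            comps.setdefault(find(i), []).append(name)
        groups = [g for g in comps.values() if len(g) >= 2]
        groups.sort(key=lambda g: names.index(g[0]))
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    return CorrelationGroups(
        correlation_matrix=matrix.correlation_matrix,
        groups=groups,
        threshold=threshold,
    )


def _within_class_scatter(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    sw = np.zeros((X.shape[1], X.shape[1]))
    for lab in (-1, 1):
        Xl = X[labels == lab]
        centred = Xl - Xl.mean(axis=0)
        sw += centred.T @ centred
    return sw


def fisher_lda(
    table: FeatureTable,
    group: list[str],
    group_name: str = "LDA",
    ridge_rel: float = RIDGE_REL,
) -> LdaProjection:
    """Two-class Fisher discriminant projection of a feature group.

    Coefficients are proportional to S_W⁻¹(μ₊ − μ₋), normalised to unit
    Euclidean length and sign-fixed so the projected patient mean exceeds
    the projected control mean. A small ridge (relative to trace(S_W)/p)
    stabilises exactly collinear groups.
    """
    if len(group) < 2:
        raise ValueError("a group must contain at least 2 features")
    if not table.both_classes_present():
        raise ValueError("both classes required for a discriminant direction")
    X = table.matrix(group)
    labels = table.labels
    sw = _within_class_scatter(X, labels)
    p = sw.shape[0]
    sw_ridged = sw + ridge_rel * (np.trace(sw) / p) * np.eye(p)
    delta = X[labels == 1].mean(axis=0) - X[labels == -1].mean(axis=0)
    try:
        w = np.linalg.solve(sw_ridged, delta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"within-class scatter of group {group} singular even after ridge"
        ) from exc
    norm = np.linalg.norm(w)
    if not np.isfinite(norm) or norm == 0.0:
        raise np.linalg.LinAlgError(
            f"degenerate discriminant direction for group {group}"
        )
    w = w / norm
    proj = X @ w
    if proj[labels == 1].mean() < proj[labels == -1].mean():
        w = -w
        proj = -proj
    return LdaProjection(group_name, list(group), w, proj)


def fisher_criterion(
    table: FeatureTable, group: list[str], direction: np.ndarray
) -> float:
    """Between-class over within-class variance of a projection direction."""
    X = table.matrix(group)
    labels = table.labels
    direction = np.asarray(direction, dtype=float)
    proj = X @ direction
    mu_pos = proj[labels == 1].mean()
    mu_neg = proj[labels == -1].mean()
    within = _within_class_scatter(proj[:, None], labels)[0, 0]
    if within == 0.0:
        return np.inf
    return float((mu_pos - mu_neg) ** 2 / within)


def apply_projection(
    table: FeatureTable,
    coefficients: np.ndarray,
    members: list[str],
    new_name: str,
) -> FeatureTable:
    """Append the rowwise dot product of members and coefficients as a column."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (len(members),):
        raise ValueError(
            f"{coefficients.size} coefficients for {len(members)} member features"
        )
    proj = table.matrix(members) @ coefficients
    return table.with_column(new_name, proj)


def append_group_projections(
    table: FeatureTable, mode: str = "reference"
) -> FeatureTable:
    """Append MDVP-LDA, Shimmer-LDA and Nonlinear-LDA columns to a table.

    ``mode='reference'`` uses the fixed reference coefficient vectors;
    ``mode='fit'`` fits fresh Fisher directions on the table itself.
    """
    out = table
    for name, members in PREDEFINED_GROUPS.items():
        if mode == "reference":
            coeffs = np.asarray(REFERENCE_LDA_COEFFICIENTS[name])
        elif mode == "fit":
            coeffs = fisher_lda(out, members, group_name=name).coefficients
        else:
            raise ValueError(f"unknown projection mode {mode!r}")
        out = apply_projection(out, coeffs, members, name)
    return out
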