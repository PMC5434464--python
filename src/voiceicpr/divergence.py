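"""Class-overlap feature selection: ICPR and symmetric KL divergence.

Two filter statistics compare the class-conditional densities of a single
feature:

* **ICPR** (interclass probability risk) — the integral of the pointwise
  minimum of the two densities, i.e. the probability mass where the classes
  overlap. 1 for identical distributions, 0 for disjoint support; features
  with small ICPR are easy to separate. Densities overlapping at a
  random-guess level (overlap mass equal to the total non-overlap mass)
  give ICPR = 2/3.

* **MKLD** (modified Kullback–Leibler divergence) — the sum of both
  directed relative entropies, a symmetric divergence that is 0 for
  identical densities and grows with class separation; the random-guess
  level corresponds to MKLD around 1.

Selection keeps features with ICPR strictly below ``icpr_max`` (default
0.6) or MKLD strictly above ``mkld_min`` (default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable
from .density import (
    DEFAULT_GRID_SIZE,
    DensityEstimate,
    estimate_pdf,
    evaluation_grid,
    optimal_bandwidth,
)

__all__ = ["FeatureDivergence", "DivergenceReport", "icpr", "mkld", "rank_and_select"]

#: Relative floor applied to densities inside MKLD logarithms; the directed
#: relative entropies are undefined where either density is exactly zero.
MKLD_FLOOR_REL = 1e-12

ICPR_MAX_DEFAULT = 0.6
MKLD_MIN_DEFAULT = 1.0


def _check_shared_grid(pdf_a: DensityEstimate, pdf_b: DensityEstimate) -> None:
    if pdf_a.grid.shape != pdf_b.grid.shape or not np.array_equal(
        pdf_a.grid, pdf_b.grid
    ):
        raise ValueError("density estimates must share one evaluation grid")


def icpr(pdf_a: DensityEstimate, pdf_b: DensityEstimate) -> float:
    """Interclass probability risk: overlap mass of two densities.

    Trapezoidal integral over the shared grid of min(f_a, f_b); symmetric
    in its arguments and confined to [0, 1] for normalised densities.
    """
    _check_shared_grid(pdf_a, pdf_b)
    return float(
        np.trapezoid(np.minimum(pdf_a.density, pdf_b.density), pdf_a.grid)
    )


def mkld(pdf_a: DensityEstimate, pdf_b: DensityEstimate) -> float:
    """Symmetric (two-way) Kullback–Leibler divergence between densities.

    Both directed relative-entropy integrals are computed by the trapezoid
    rule on the shared grid and summed. A relative floor keeps the log
    arguments positive where a density underflows to zero; each integrand
    term f*log(f/g) is taken as 0 where f itself vanishes.
    """
    _check_shared_grid(pdf_a, pdf_b)
    fa, fb = pdf_a.density, pdf_b.density
    eps = MKLD_FLOOR_REL * max(fa.max(), fb.max())
    fa_f = np.maximum(fa, eps)
    fb_f = np.maximum(fb, eps)
    log_ratio = np.log(fa_f) - np.log(fb_f)
    term_ab = np.where(fa > 0, fa * log_ratio, 0.0)
    term_ba = np.where(fb > 0, -fb * log_ratio, 0.0)
    return float(np.trapezoid(term_ab, pdf_a.grid) + np.trapezoid(term_ba, pdf_a.grid))


@dataclass(frozen=True)
class FeatureDivergence:
    """Per-feature selection record."""

    feature_name: str
    icpr: float
    mkld: float
    selected_by_icpr: bool
    selected_by_mkld: bool
    note: str = ""

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.icpr)


@dataclass
class DivergenceReport:
    """Ranked divergence records plus the thresholds that produced them."""

    records: list[FeatureDivergence]
    icpr_max: float = ICPR_MAX_DEFAULT
    mkld_min: float = MKLD_MIN_DEFAULT
    grid_size: int = DEFAULT_GRID_SIZE

    @property
    def selected_by_icpr(self) -> list[str]:
        return [r.feature_name for r in self.records if r.selected_by_icpr]

    @property
    def selected_by_mkld(self) -> list[str]:
        return [r.feature_name for r in self.records if r.selected_by_mkld]

    def record(self, feature_name: str) -> FeatureDivergence:
        for r in self.records:
            if r.feature_name == feature_name:
                return r
        raise KeyError(f"no record for feature {feature_name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [r.feature_name for r in self.records],
                "icpr": [r.icpr for r in self.records],
                "mkld": [r.mkld for r in self.records],
                "selected_icpr": [r.selected_by_icpr for r in self.records],
                "selected_mkld": [r.selected_by_mkld for r in self.records],
            }
        )


def class_densities(
    table: FeatureTable, feature: str, n_grid: int = DEFAULT_GRID_SIZE
) -> tuple[DensityEstimate, DensityEstimate]:
    """Patient (+1) and control (-1) Parzen densities on a shared grid."""
    pos = table.class_values(feature, 1)
    neg = table.class_values(feature, -1)
    grid = evaluation_grid(pos, neg, n_grid)
    pdf_pos = estimate_pdf(pos, grid, optimal_bandwidth(pos), class_label=1)
    pdf_neg = estimate_pdf(neg, grid, optimal_bandwidth(neg), class_label=-1)
    return pdf_pos, pdf_neg


def rank_and_select(
    table: FeatureTable,
    candidate_features: list[str] | None = None,
    icpr_max: float = ICPR_MAX_DEFAULT,
    mkld_min: float = MKLD_MIN_DEFAULT,
    n_grid: int = DEFAULT_GRID_SIZE,
) -> DivergenceReport:
    """Score every candidate feature by ICPR and MKLD and apply thresholds.

    Selection uses strict inequalities (ICPR < ``icpr_max``,
    MKLD > ``mkld_min``); records are ordered by ascending ICPR, so the
    most separable features come first. A degenerate (zero-spread) feature
    is recorded with NaN statistics and a diagnostic note rather than
    raising.
    """
    if candidate_features is None:
        candidate_features = list(table.feature_names)
    missing = [f for f in candidate_features if f not in table.feature_names]
    if missing:
        raise KeyError(f"candidate features not in table: {missing}")
    if not table.both_classes_present():
        raise ValueError("both classes must be present for divergence ranking")

    records = []
    for name in candidate_features:
        try:
            pdf_pos, pdf_neg = class_densities(table, name, n_grid)
        except ValueError as exc:
            records.append(
                FeatureDivergence(name, float("nan"), float("nan"), False, False,
                                  note=f"unselectable: {exc}")
            )
            continue
        v_icpr = icpr(pdf_pos, pdf_neg)
        v_mkld = mkld(pdf_pos, pdf_neg)
        records.append(
            FeatureDivergence(
                feature_name=name,
                icpr=v_icpr,
                mkld=v_mkld,
                selected_by_icpr=bool(v_icpr < icpr_max),
                selected_by_mkld=bool(v_mkld > mkld_min),
            )
        )
    records.sort(key=lambda r: (np.isnan(r.icpr), r.icpr))
    return DivergenceReport(records, icpr_max=icpr_max, mkld_min=mkld_min,
                            grid_size=n_grid)
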