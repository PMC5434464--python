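"""Parzen-window estimation of class-conditional feature densities.

A univariate kernel density estimate with a Gaussian kernel,

    f_hat(x) = (1 / (N h)) * sum_i phi((x - x_i) / h),

evaluated on a fixed uniform grid. The bandwidth follows the normal
reference rule h = 1.06 * SD * N^(-1/5). Densities are evaluated, never
renormalised: the integral-close-to-one property on a grid extending four
bandwidths beyond the data is asserted by callers as a correctness check,
and renormalising would mask grid-construction bugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityEstimate",
    "optimal_bandwidth",
    "evaluation_grid",
    "estimate_pdf",
    "scott_bin_count",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: Default number of grid points for density evaluation and quadrature.
DEFAULT_GRID_SIZE = 512

#: Grid margin beyond the pooled data range, in units of the larger bandwidth.
GRID_MARGIN_BANDWIDTHS = 4.0


@dataclass(frozen=True)
class DensityEstimate:
    """An evaluated density curve on an ordered grid.

    ``density[i]`` is the Parzen estimate at ``grid[i]``; ``bandwidth`` is
    the kernel width h used and ``n_points`` the sample size N.
    ``class_label`` (+1/-1/None) records which class the curve describes.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_points: int
    class_label: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if self.grid.shape != self.density.shape or self.grid.ndim != 1:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if (self.density < 0).any():
            raise ValueError("density must be nonnegative")

    def integral(self) -> float:
        """Trapezoidal integral of the curve over its grid."""
        return float(np.trapezoid(self.density, self.grid))


def optimal_bandwidth(values: np.ndarray) -> float:
    """Normal-reference kernel bandwidth h = 1.06 * SD * N^(-1/5).

    SD uses the unbiased (N-1) estimator. Raises ``ValueError`` for fewer
    than two values or a zero-spread (degenerate) sample.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"need at least 2 values to set a bandwidth, got {n}")
    sd = float(np.std(values, ddof=1))
    if sd <= 0.0:
        raise ValueError("all values identical: zero standard deviation")
    return 1.06 * sd * n ** (-1.0 / 5.0)


def evaluation_grid(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_grid: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Shared uniform grid covering both samples plus a 4-bandwidth margin.

    The margin uses the larger of the two normal-reference bandwidths so
    that both density tails are negligible at the grid edges.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size == 0 or values_b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_grid < 64:
        raise ValueError(f"n_grid must be at least 64, got {n_grid}")
    h = max(optimal_bandwidth(values_a), optimal_bandwidth(values_b))
    lo = min(values_a.min(), values_b.min()) - GRID_MARGIN_BANDWIDTHS * h
    hi = max(values_a.max(), values_b.max()) + GRID_MARGIN_BANDWIDTHS * h
    return np.linspace(lo, hi, n_grid)


def estimate_pdf(
    values: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    class_label: int | None = None,
) -> DensityEstimate:
    """Evaluate the Gaussian-kernel Parzen estimate on ``grid``."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate a density from no values")
    if bandwidth <= 0.0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if grid.ndim != 1 or (np.diff(grid) < 0).any():
        raise ValueError("grid must be a sorted 1-D array")
    u = (grid[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (values.size * bandwidth * _SQRT2PI)
    return DensityEstimate(
        grid=grid,
        density=dens,
        bandwidth=float(bandwidth),
        n_points=int(values.size),
        class_label=class_label,
    )


def scott_bin_count(values: np.ndarray) -> int:
    """Histogram bin count by Scott's rule (display convenience only)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    width = 3.5 * np.std(values, ddof=1) * n ** (-1.0 / 3.0)
    if width <= 0:
        raise ValueError("zero-spread sample")
    return max(1, int(np.ceil((values.max() - values.min()) / width)))
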