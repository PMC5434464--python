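from pathlib import Path

import numpy as np
import pytest
from scipy.stats import norm

from voiceicpr.data import SyntheticSpec, generate_synthetic_cohort
from voiceicpr.density import DensityEstimate

#: Location where a user-supplied copy of the UCI Parkinsons file is expected.
UCI_PATH = Path(__file__).resolve().parent.parent / "data" / "parkinsons.data"

#: One designed informative feature per correlated block (3-SD class shift,
#: true-density ICPR = 2*Phi(-1.5) ~= 0.13); all other features null.
DESIGNED_FEATURES = ["MDVP:Jitter(%)", "MDVP:Shimmer", "DFA"]
DESIGNED_SHIFT = 3.0


def informative_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        class_shift={f: DESIGNED_SHIFT for f in DESIGNED_FEATURES}, seed=seed
    )


@pytest.fixture
def informative_cohort():
    return generate_synthetic_cohort(informative_spec(seed=11))


@pytest.fixture
def null_cohort():
    """Blocks present, no class difference anywhere."""
    return generate_synthetic_cohort(SyntheticSpec(seed=7))


def true_gaussian_density(grid: np.ndarray, mean: float, sd: float = 1.0,
                          n_points: int = 1000) -> DensityEstimate:
    """An exact normal density placed on a grid, as a DensityEstimate."""
    return DensityEstimate(
        grid=grid, density=norm.pdf(grid, mean, sd), bandwidth=sd, n_points=n_points
    )
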