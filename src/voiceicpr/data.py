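"""Feature tables for sustained-vowel voice recordings.

The central container is :class:`FeatureTable`: one row per recording, 22
named acoustic features (jitter/shimmer perturbations, noise ratios, and
nonlinear dynamics measures), a binary class label (+1 for idiopathic
Parkinson's disease, -1 for healthy control) and a subject identifier.
Tables are read from the UCI "Parkinsons" CSV dialect and written back in
the same dialect; a synthetic generator draws two-class cohorts with the
block-correlation structure that real jitter/shimmer panels exhibit.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_FEATURES",
    "FEATURE_ALIASES",
    "FeatureTable",
    "SyntheticSpec",
    "read_voice_csv",
    "write_voice_csv",
    "generate_synthetic_cohort",
    "write_report",
    "read_report",
]

#: Canonical names of the 22 vocal features, in the conventional order.
CANONICAL_FEATURES = [
    "MDVP:F0",
    "MDVP:Fhi",
    "MDVP:Flo",
    "MDVP:Jitter(%)",
    "MDVP:Jitter(Abs)",
    "MDVP:RAP",
    "MDVP:PPQ",
    "Jitter:DDP",
    "MDVP:Shimmer",
    "MDVP:Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "MDVP:APQ11",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "DFA",
    "D2",
    "Spread1",
    "Spread2",
    "PPE",
]

#: Map from the UCI file's header spellings to the canonical names above.
FEATURE_ALIASES = {
    "MDVP:Fo(Hz)": "MDVP:F0",
    "MDVP:Fhi(Hz)": "MDVP:Fhi",
    "MDVP:Flo(Hz)": "MDVP:Flo",
    "MDVP:APQ": "MDVP:APQ11",
    "spread1": "Spread1",
    "spread2": "Spread2",
}

_UCI_ALIASES_INV = {v: k for k, v in FEATURE_ALIASES.items()}

_SUBJECT_RE = re.compile(r"^(?P<subject>.+)_\d+$")


def _subject_of(name: str) -> str:
    """Subject ID = recording name minus its trailing ``_<index>``."""
    m = _SUBJECT_RE.match(name)
    return m.group("subject") if m else name


@dataclass
class FeatureTable:
    """Recordings x features matrix with +1/-1 class labels.

    Parameters
    ----------
    feature_names
        Unique, ordered column names.
    values
        Array of shape ``(n_rows, n_features)``; no missing values.
    labels
        Per-row class label, +1 (patient) or -1 (control).
    subject_ids
        Per-row subject identifier (several recordings may share one).
    single_class
        Diagnostic flag set by the loader when only one class is present.
    """

    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    single_class: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_names = list(self.feature_names)
        self.subject_ids = list(self.subject_ids)
        n, p = self.values.shape
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError(
                f"row mismatch: {n} value rows, {len(self.labels)} labels, "
                f"{len(self.subject_ids)} subject ids"
            )
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at row {r}, feature {self.feature_names[c]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None
        return self.values[:, j]

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Column-subset of ``values`` in the given order."""
        return np.column_stack([self.column(n) for n in names])

    def class_values(self, name: str, label: int) -> np.ndarray:
        """Values of one feature restricted to one class."""
        return self.column(name)[self.labels == label]

    def both_classes_present(self) -> bool:
        return bool((self.labels == 1).any() and (self.labels == -1).any())

    def with_column(self, name: str, values: np.ndarray) -> "FeatureTable":
        """Return a copy with one extra feature column appended."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_rows,):
            raise ValueError(
                f"column {name!r} has shape {values.shape}, expected ({self.n_rows},)"
            )
        return FeatureTable(
            feature_names=self.feature_names + [name],
            values=np.column_stack([self.values, values]),
            labels=self.labels.copy(),
            subject_ids=list(self.subject_ids),
            single_class=self.single_class,
        )

    def subset_rows(self, index: np.ndarray) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            feature_names=list(self.feature_names),
            values=self.values[index],
            labels=self.labels[index],
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(index).tolist()]
            if index.dtype != bool
            else [s for s, keep in zip(self.subject_ids, index) if keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject", self.subject_ids)
        df["label"] = self.labels
        return df


def read_voice_csv(
    path: str | Path,
    label_column: str = "status",
    positive_value: object = 1,
    name_column: str = "name",
) -> FeatureTable:
    """Load a feature table from the UCI Parkinsons CSV dialect.

    The ``name`` column is routed to ``subject_ids`` (subject = prefix of
    the recording name before the final ``_<index>``); the label column is
    mapped to +1 where it equals ``positive_value`` and -1 elsewhere; the
    remaining numeric columns become features, with dialect spellings
    (e.g. ``MDVP:Fo(Hz)``) renamed to canonical ones (``MDVP:F0``).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found in {path.name}; "
            f"columns are {list(df.columns)}"
        )
    if name_column in df.columns:
        names = df[name_column].astype(str).tolist()
        subject_ids = [_subject_of(n) for n in names]
        df = df.drop(columns=[name_column])
    else:
        subject_ids = [f"row{i}" for i in range(len(df))]

    raw_labels = df[label_column]
    labels = np.where(raw_labels == positive_value, 1, -1)
    df = df.drop(columns=[label_column])
    df = df.rename(columns=FEATURE_ALIASES)

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row} of {path.name}"
            )
        df[col] = coerced

    table = FeatureTable(
        feature_names=list(df.columns),
        values=df.to_numpy(dtype=float),
        labels=labels,
        subject_ids=subject_ids,
    )
    if not table.both_classes_present():
        warnings.warn(f"{path.name} contains a single class only", stacklevel=2)
        table.single_class = True
    return table


def write_voice_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a table in the UCI dialect (name, features, status in {0,1})."""
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df = df.rename(columns=_UCI_ALIASES_INV)
    counts: dict[str, int] = {}
    names = []
    for s in table.subject_ids:
        counts[s] = counts.get(s, 0) + 1
        names.append(f"{s}_{counts[s]}")
    df.insert(0, "name", names)
    df["status"] = (table.labels == 1).astype(int)
    # 17 significant digits guarantee bit-exact float round trips
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: Default block structure mirroring the jitter, shimmer and nonlinear
#: correlation blocks of the real 22-feature panel.
DEFAULT_BLOCKS = [
    (
        [
            "MDVP:Jitter(%)",
            "MDVP:Jitter(Abs)",
            "MDVP:RAP",
            "MDVP:PPQ",
            "Jitter:DDP",
            "NHR",
        ],
        0.95,
    ),
    (
        [
            "MDVP:Shimmer",
            "MDVP:Shimmer(dB)",
            "Shimmer:APQ3",
            "Shimmer:APQ5",
            "MDVP:APQ11",
            "Shimmer:DDA",
        ],
        0.95,
    ),
    (["DFA", "PPE"], 0.95),
]


@dataclass
class SyntheticSpec:
    """Recipe for a two-class synthetic voice cohort.

    Each class is drawn from a multivariate Gaussian with block-equicorrelated
    structure; the patient class may instead be a two-component equal-variance
    Gaussian mixture (bimodal marginals, as nonlinear voice measures such as
    RPDE show in patients). Class differences are parameterised per feature
    as a location shift (``class_shift``, in control-SD units) and an SD
    ratio (``class_scale``).

    Defaults emulate the real cohort: 48 control and 147 patient recordings
    and three highly correlated blocks (six jitter-type features with NHR,
    six shimmer-type features, DFA with PPE) at within-block r = 0.95.
    """

    n_control: int = 48
    n_patient: int = 147
    block_definitions: list[tuple[list[str], float]] = field(
        default_factory=lambda: [(list(b), r) for b, r in DEFAULT_BLOCKS]
    )
    extra_features: list[str] = field(default_factory=list)
    class_shift: dict[str, float] = field(default_factory=dict)
    class_scale: dict[str, float] = field(default_factory=dict)
    patient_mixture_weight: float = 0.0
    patient_mixture_shift: float = 2.0
    seed: int = 0

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for block, _ in self.block_definitions:
            names.extend(block)
        names.extend(self.extra_features)
        return names

    def correlation_matrix(self) -> np.ndarray:
        names = self.feature_names
        p = len(names)
        corr = np.eye(p)
        start = 0
        for block, rho in self.block_definitions:
            k = len(block)
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"within-block correlation {rho} outside [0, 1)")
            corr[start : start + k, start : start + k] = rho
            np.fill_diagonal(corr[start : start + k, start : start + k], 1.0)
            start += k
        return corr


def generate_synthetic_cohort(spec: SyntheticSpec) -> FeatureTable:
    """Draw a two-class cohort according to ``spec``.

    Deterministic for a fixed ``spec.seed``. Raises if the requested
    block-correlation matrix is not positive definite.
    """
    if spec.n_control <= 0 or spec.n_patient <= 0:
        raise ValueError("class counts must be positive")
    names = spec.feature_names
    if len(set(names)) != len(names):
        raise ValueError("block/extra feature names must be disjoint")
    if not names:
        raise ValueError("spec defines no features")
    corr = spec.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("requested correlation matrix is not positive definite")

    rng = np.random.default_rng(spec.seed)
    p = len(names)
    shift = np.array([spec.class_shift.get(n, 0.0) for n in names])
    scale = np.array([spec.class_scale.get(n, 1.0) for n in names])

    z_co = rng.standard_normal((spec.n_control, p)) @ chol.T
    z_pd = rng.standard_normal((spec.n_patient, p)) @ chol.T * scale + shift
    if spec.patient_mixture_weight > 0.0:
        in_second = rng.random(spec.n_patient) < spec.patient_mixture_weight
        z_pd[in_second] += spec.patient_mixture_shift

    values = np.vstack([z_co, z_pd])
    labels = np.concatenate(
        [-np.ones(spec.n_control, dtype=int), np.ones(spec.n_patient, dtype=int)]
    )
    subjects = [f"synthC{i:03d}" for i in range(spec.n_control)] + [
        f"synthP{i:03d}" for i in range(spec.n_patient)
    ]
    return FeatureTable(names, values, labels, subjects)


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------


def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Write a divergence report or evaluation summary to CSV or JSON.

    Numeric fields round-trip at full precision (reading the file back
    reproduces the values bit for bit).
    """
    path = Path(path)
    if hasattr(report, "to_dataframe"):
        df = report.to_dataframe()
        if df.empty:
            raise ValueError("refusing to write an empty report")
        if format == "csv":
            df.to_csv(path, index=False, float_format="%.17g")
        elif format == "json":
            # stdlib json uses shortest round-trip float repr
            path.write_text(json.dumps(df.to_dict(orient="records")))
        else:
            raise ValueError(f"unknown format {format!r}")
    elif isinstance(report, dict):
        if not report:
            raise ValueError("refusing to write an empty report")
        if format == "json":
            path.write_text(json.dumps(report, indent=2, default=float))
        elif format == "csv":
            pd.DataFrame([report]).to_csv(path, index=False, float_format="%.17g")
        else:
            raise ValueError(f"unknown format {format!r}")
    else:
        raise TypeError(f"cannot serialise report of type {type(report).__name__}")


def read_report(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path, float_precision="round_trip")
    if format == "json":
        obj = json.loads(path.read_text())
        return pd.DataFrame([obj] if isinstance(obj, dict) else obj)
    raise ValueError(f"unknown format {format!r}")
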