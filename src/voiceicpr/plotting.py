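"""Plot helpers: class-density overlap, bagging error curves, ROC curves."""

from __future__ import annotations

import numpy as np

from .density import DensityEstimate
from .evaluate import RocCurve


def plot_class_densities(
    pdf_patient: DensityEstimate, pdf_control: DensityEstimate, ax=None, title=""
):
    """Overlay the two class densities and shade the ICPR overlap area."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pdf_control.grid, pdf_control.density, color="tab:blue", label="control")
    ax.plot(pdf_patient.grid, pdf_patient.density, color="tab:red", label="patient")
    overlap = np.minimum(pdf_control.density, pdf_patient.density)
    ax.fill_between(pdf_control.grid, overlap, color="gray", alpha=0.6,
                    label="overlap (ICPR)")
    ax.set_xlabel("feature value")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_error_curve(errors: np.ndarray, ax=None, label=""):
    """Resubstitution error of the first-t-trees vote against t."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(1, len(errors) + 1), errors, label=label or None)
    ax.set_xlabel("number of bagged trees")
    ax.set_ylabel("error rate")
    if label:
        ax.legend()
    return ax


def plot_roc(curve: RocCurve, ax=None, label=""):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lbl = f"{label} (AUC={curve.auc:.4f})" if label else f"AUC={curve.auc:.4f}"
    ax.plot(curve.fpr, curve.tpr, label=lbl)
    ax.plot([0, 1], [0, 1], linestyle=":", color="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax
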