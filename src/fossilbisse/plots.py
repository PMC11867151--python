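"""Small matplotlib helpers mirroring the study's figure types.

These are conveniences for inspecting desk-scale runs (density ridges of
posterior means, relative-error boxplots, inequality-probability
histograms, ROC curves); styling is deliberately plain.
"""

from __future__ import annotations

import numpy as np


def posterior_mean_densities(ax, means_by_set: dict[str, list[float]], truth: float | None = None):
    """Overlaid histograms of posterior means, one per analysis set."""
    for label, means in means_by_set.items():
        ax.hist(means, bins=20, density=True, histtype="step", label=label)
    if truth is not None:
        ax.axvline(truth, color="k", ls="--", lw=1)
    ax.legend(fontsize=8)
    return ax


def relative_error_boxplot(ax, errors_by_set: dict[str, list[float]]):
    labels = list(errors_by_set)
    ax.boxplot([errors_by_set[k] for k in labels], tick_labels=labels)
    ax.axhline(0.0, color="k", ls="--", lw=1)
    ax.set_ylabel("signed relative error")
    return ax


def probability_histogram(ax, probs, label: str = ""):
    ax.hist(np.asarray(list(probs)), bins=np.linspace(0, 1, 21), label=label or None)
    ax.set_xlabel("posterior probability")
    return ax


def roc_curve(ax, roc_df, label: str = ""):
    auc = roc_df.attrs.get("auc")
    lab = f"{label} (AUC={auc:.2f})" if auc is not None else label
    ax.plot(roc_df["fpr"], roc_df["tpr"], label=lab or None)
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(fontsize=8)
    return ax
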