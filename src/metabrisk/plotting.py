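"""Basic score-plot and ROC figures (cosmetic; not used by the pipeline)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def score_plot(results, x, y, ax=None):
    """Predictive vs first orthogonal OPLS-DA score, coloured by class.

    With no orthogonal component the y-axis is the continuous response.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = results.predictive_scores(x)
    if results.k_ortho:
        xs = results._prepare(x)
        t_o = xs @ results.ortho_weights[:, 0]
        ylab = "orthogonal score 1"
    else:
        t_o = results.decision_function(x)
        ylab = "predicted response"
    y = np.asarray(y)
    for cls, marker in zip(results.classes, "oX"):
        m = y == cls
        ax.scatter(t[m], t_o[m], label=str(cls), marker=marker, alpha=0.8)
    ax.set_xlabel("predictive score")
    ax.set_ylabel(ylab)
    ax.legend()
    return ax


def roc_plot(fpr, tpr, auc, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax
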