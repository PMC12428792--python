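"""Simple diagnostic plots: the ROC curve and the score histogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt

from .roc import RocResult

__all__ = ["plot_roc", "plot_score_histogram"]


def plot_roc(result: RocResult, ax=None):
    """ROC curve with the chance diagonal; AUC and CI in the title."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    fpr = [p[0] for p in result.curve]
    tpr = [p[1] for p in result.curve]
    ax.plot(fpr, tpr, marker="o", lw=1.5, label=result.endpoint)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(
        f"AUC = {result.auc:.3f} "
        f"(95% CI {result.ci_low:.3f}-{result.ci_high:.3f})"
    )
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    return ax


def plot_score_histogram(points, ax=None):
    """Frequency of each composite-score point total (0-6)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.hist(points, bins=[b - 0.5 for b in range(8)], rwidth=0.85, color="#4477aa")
    ax.set_xlabel("EXPoSURE points")
    ax.set_ylabel("patients")
    ax.set_xticks(range(7))
    return ax
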