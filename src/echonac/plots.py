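"""Plot helpers: residual-tumor trajectories and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_residual_summary(summary, ax=None):
    """Line plot of mean Ratio N per cycle for the pCR and non-pCR groups.

    ``summary`` is the frame from
    :func:`echonac.response.group_residual_summary`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for group, sub in summary.groupby("group"):
        sub = sub.sort_values("cycle")
        ax.errorbar(sub["cycle"], sub["mean_ratio"], yerr=sub["sd_ratio"],
                    marker="o", capsize=3, label=group)
    ax.set_xlabel("NAC cycle")
    ax.set_ylabel("residual tumor size ratio")
    ax.set_ylim(bottom=0)
    ax.legend()
    return ax


def plot_roc(roc_results: dict, ax=None):
    """Overlay ROC curves; ``roc_results`` maps label -> ROCResult."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for label, roc in roc_results.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    return ax
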