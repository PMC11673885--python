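"""Figure rendering: per-grade count plots with CI whiskers, confusion matrix."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from lesioncount.classify import ClassifierReport
from lesioncount.types import GRADES

_GRADE_ORDER = [g.label for g in GRADES]


def severity_plot(summaries: pd.DataFrame, path, title: str | None = None) -> None:
    """Point plot of mean +/- 95% CI per grade, one panel per measure.

    Accepts either the per-dataset summary frame (column ``mean``) or the
    weighted cross-dataset frame (column ``pooled_mean``).
    """
    frame = summaries.copy()
    value_col = "pooled_mean" if "pooled_mean" in frame.columns else "mean"
    lesions = [m for m in ("MA", "Hma", "RL", "HE") if (frame["lesion"] == m).any()]
    fig, axes = plt.subplots(1, max(len(lesions), 1), figsize=(3.2 * len(lesions), 3.2),
                             squeeze=False, sharex=True)
    for ax, lesion in zip(axes[0], lesions):
        sub = frame[frame["lesion"] == lesion]
        groups = sub.groupby("dataset_id") if "dataset_id" in sub.columns else [("all", sub)]
        for name, g in groups:
            g = g.set_index("grade").reindex(_GRADE_ORDER).dropna(subset=[value_col])
            x = [_GRADE_ORDER.index(i) for i in g.index]
            y = g[value_col].to_numpy()
            err = np.vstack([y - g["ci_low"], g["ci_high"] - y])
            ax.errorbar(x, y, yerr=np.clip(err, 0, None), marker="o", capsize=3, label=str(name))
        ax.set_title(lesion)
        ax.set_xticks(range(len(_GRADE_ORDER)), _GRADE_ORDER, rotation=45)
        ax.set_ylabel("count / image")
    if len(lesions) and len(frame.get("dataset_id", pd.Series(dtype=str)).unique()) > 1:
        axes[0][-1].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def confusion_plot(report: ClassifierReport, path) -> None:
    """Heatmap of the 4x4 confusion matrix with a per-class sensitivity column."""
    fig, ax = plt.subplots(figsize=(4.6, 4))
    ax.imshow(report.confusion, cmap="Blues")
    labels = _GRADE_ORDER
    ax.set_xticks(range(4), labels, rotation=45)
    ax.set_yticks(range(4), labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(4):
        for j in range(4):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center", fontsize=9)
        sens = report.sensitivity[i]
        ax.text(3.8, i, "-" if np.isnan(sens) else f"{sens:.2f}",
                ha="left", va="center", fontsize=9, color="tab:red")
    ax.set_title(f"accuracy {report.accuracy:.3f} (n_test={report.n_test})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
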