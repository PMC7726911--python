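"""Summary plots for evaluation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import EvalReport

__all__ = ["plot_report"]


def plot_report(report: EvalReport, path: str | Path, title: str = "") -> Path:
    """Per-ligand ROC and PR curves: gray lines per ligand, red median,
    shaded 40-60 percentile band."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    grid = report.quantile_band["grid"]

    ax = axes[0]
    for c in report.per_ligand.values():
        ax.plot(c.fpr, c.tpr, color="0.7", lw=0.6, zorder=1)
    ax.fill_between(
        grid,
        report.quantile_band["tpr_q40"],
        report.quantile_band["tpr_q60"],
        color="lightgreen",
        alpha=0.6,
        zorder=2,
    )
    ax.plot(grid, report.quantile_band["tpr_median"], color="red", lw=1.5, zorder=3)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(
        f"AUROC mean {report.mean_auroc:.3f} / median {report.median_auroc:.3f}"
    )

    ax = axes[1]
    for c in report.per_ligand.values():
        ax.plot(c.recall, c.precision, color="0.7", lw=0.6, zorder=1)
    ax.fill_between(
        grid,
        report.quantile_band["precision_q40"],
        report.quantile_band["precision_q60"],
        color="lightgreen",
        alpha=0.6,
        zorder=2,
    )
    ax.plot(
        grid, report.quantile_band["precision_median"], color="red", lw=1.5, zorder=3
    )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_title(
        f"AUPRC mean {report.mean_auprc:.3f} / median {report.median_auprc:.3f}"
    )
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
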