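"""Per-ligand ROC / precision-recall evaluation and permutation controls.

Following the evaluation protocol for ligand-receptor prediction, test
samples are grouped by their first gene (the ligand, or the putative
source gene for the direction task); an ROC and a precision-recall curve
are computed per ligand, and the per-ligand areas are aggregated as mean
and median.  Ligands whose test samples do not contain both a positive and
a negative are excluded from aggregation (and counted).  The 40th and 60th
percentiles of the true-positive rate (precision) across ligands are
computed along a fixed 101-point false-positive-rate (recall) grid to give
the quantile band drawn around the median curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .labels import PairSample

__all__ = ["LigandCurves", "EvalReport", "per_ligand_curves", "merge_reports"]

_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class LigandCurves:
    """Curves and areas for one ligand's test samples."""

    ligand: str
    auroc: float
    auprc: float
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class EvalReport:
    """Aggregated per-ligand evaluation."""

    per_ligand: dict[str, LigandCurves]
    mean_auroc: float
    median_auroc: float
    mean_auprc: float
    median_auprc: float
    quantile_band: dict[str, np.ndarray]
    n_curves: int
    n_excluded: int
    control: str | None = None
    extra: dict = field(default_factory=dict)

    def aurocs(self) -> np.ndarray:
        return np.array([c.auroc for c in self.per_ligand.values()])

    def auprcs(self) -> np.ndarray:
        return np.array([c.auprc for c in self.per_ligand.values()])

    def to_dict(self) -> dict:
        return {
            "mean_auroc": self.mean_auroc,
            "median_auroc": self.median_auroc,
            "mean_auprc": self.mean_auprc,
            "median_auprc": self.median_auprc,
            "n_curves": self.n_curves,
            "n_excluded": self.n_excluded,
            "control": self.control,
            "per_ligand": {
                lig: {
                    "auroc": c.auroc,
                    "auprc": c.auprc,
                    "n_pos": c.n_pos,
                    "n_neg": c.n_neg,
                }
                for lig, c in sorted(self.per_ligand.items())
            },
            "quantile_band": {
                k: np.asarray(v).tolist() for k, v in self.quantile_band.items()
            },
            "extra": self.extra,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _interp_roc(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    return np.interp(_GRID, fpr, tpr)


def _interp_pr(recall: np.ndarray, precision: np.ndarray) -> np.ndarray:
    order = np.argsort(recall)
    return np.interp(_GRID, recall[order], precision[order])


def per_ligand_curves(
    samples: Sequence[PairSample], probs: Sequence[float]
) -> EvalReport:
    """Group predictions by ligand and aggregate ROC / PR areas.

    AUROC uses the rank statistic (ties count one half); AUPRC is the
    step-wise precision-recall integration without interpolation.
    """
    probs = np.asarray(probs, dtype=float)
    if len(samples) != len(probs):
        raise ValueError("samples and probabilities differ in length")
    by_ligand: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        # direction samples come in couples {(L,R,1), (R,L,0)}; both are
        # keyed by the true ligand L so each couple forms one curve
        key = s.gene_b if (s.task == "direction" and s.label == 0) else s.gene_a
        by_ligand.setdefault(key, []).append(i)

    curves: dict[str, LigandCurves] = {}
    excluded = 0
    for ligand, idx in by_ligand.items():
        y = np.array([samples[i].label for i in idx])
        p = probs[idx]
        if y.min() == y.max():
            excluded += 1
            continue
        fpr, tpr, _ = roc_curve(y, p)
        precision, recall, _ = precision_recall_curve(y, p)
        curves[ligand] = LigandCurves(
            ligand=ligand,
            auroc=float(roc_auc_score(y, p)),
            auprc=float(average_precision_score(y, p)),
            fpr=fpr,
            tpr=tpr,
            recall=recall,
            precision=precision,
            n_pos=int(y.sum()),
            n_neg=int(len(y) - y.sum()),
        )
    if not curves:
        raise ValueError("every ligand lacked a positive or a negative sample")

    aurocs = np.array([c.auroc for c in curves.values()])
    auprcs = np.array([c.auprc for c in curves.values()])
    tpr_stack = np.stack([_interp_roc(c.fpr, c.tpr) for c in curves.values()])
    prec_stack = np.stack(
        [_interp_pr(c.recall, c.precision) for c in curves.values()]
    )
    band = {
        "grid": _GRID.copy(),
        "tpr_q40": np.percentile(tpr_stack, 40, axis=0),
        "tpr_q60": np.percentile(tpr_stack, 60, axis=0),
        "tpr_median": np.percentile(tpr_stack, 50, axis=0),
        "precision_q40": np.percentile(prec_stack, 40, axis=0),
        "precision_q60": np.percentile(prec_stack, 60, axis=0),
        "precision_median": np.percentile(prec_stack, 50, axis=0),
    }
    return EvalReport(
        per_ligand=curves,
        mean_auroc=float(aurocs.mean()),
        median_auroc=float(np.median(aurocs)),
        mean_auprc=float(auprcs.mean()),
        median_auprc=float(np.median(auprcs)),
        quantile_band=band,
        n_curves=len(curves),
        n_excluded=excluded,
    )


def merge_reports(reports: Sequence[EvalReport], control: str | None = None) -> EvalReport:
    """Pool per-ligand curves across folds into one aggregate report.

    Gene-exclusive folds test disjoint ligand sets, so pooling simply
    unions the per-ligand entries and recomputes the aggregates.
    """
    reports = [r for r in reports if r is not None]
    if not reports:
        raise ValueError("no reports to merge")
    merged: dict[str, LigandCurves] = {}
    excluded = 0
    for r in reports:
        excluded += r.n_excluded
        for lig, c in r.per_ligand.items():
            key = lig if lig not in merged else f"{lig}#{len(merged)}"
            merged[key] = c
    aurocs = np.array([c.auroc for c in merged.values()])
    auprcs = np.array([c.auprc for c in merged.values()])
    tpr_stack = np.stack([_interp_roc(c.fpr, c.tpr) for c in merged.values()])
    prec_stack = np.stack([_interp_pr(c.recall, c.precision) for c in merged.values()])
    band = {
        "grid": _GRID.copy(),
        "tpr_q40": np.percentile(tpr_stack, 40, axis=0),
        "tpr_q60": np.percentile(tpr_stack, 60, axis=0),
        "tpr_median": np.percentile(tpr_stack, 50, axis=0),
        "precision_q40": np.percentile(prec_stack, 40, axis=0),
        "precision_q60": np.percentile(prec_stack, 60, axis=0),
        "precision_median": np.percentile(prec_stack, 50, axis=0),
    }
    return EvalReport(
        per_ligand=merged,
        mean_auroc=float(aurocs.mean()),
        median_auroc=float(np.median(aurocs)),
        mean_auprc=float(auprcs.mean()),
        median_auprc=float(np.median(auprcs)),
        quantile_band=band,
        n_curves=len(merged),
        n_excluded=excluded,
        control=control,
    )
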