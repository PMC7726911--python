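"""End-to-end experiments: graph -> folds -> training -> evaluation.

Variant naming follows the signaling interpretation of the graph operator:

* ``autocrine_plus`` uses the self-loop operator L' (neighbors and the
  cell itself),
* ``exocrine`` uses the doubly normalized Laplacian L_NN (neighbors only
  for simple graphs),
* ``diagonal`` uses the identity — a spatial-information-free control.

``run_experiment`` executes the configured task over gene-exclusive folds
(one model per fold), pools the per-ligand curves, and can persist fold
plans, checkpoints, reports, and a manifest that suffices to reproduce the
run.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__ as _pkg_version
from .evaluation import EvalReport, merge_reports, per_ligand_curves
from .expression import ExpressionMatrix
from .graph import AdjacencyMatrix, compute_adjacency, graph_matrix, permute_graph
from .labels import (
    FoldPlan,
    InteractionList,
    PairSample,
    direction_pairs,
    function_pairs,
    make_folds,
    permute_interactions,
)
from .model import TrainConfig, predict, save_checkpoint, train
from .simulate import SimulatedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANT_GRAPHS",
    "ExperimentConfig",
    "default_threshold_grid",
    "select_threshold",
    "tune_threshold",
    "run_experiment",
    "run_permutation_control",
    "run_function_task",
]

VARIANT_GRAPHS = {
    "autocrine_plus": "L_prime",
    "exocrine": "L_NN",
    "diagonal": "diagonal",
}


@dataclass
class ExperimentConfig:
    """One experiment: task, graph variant, threshold, folds, training."""

    task: str = "interaction"
    variant: str = "autocrine_plus"
    threshold: float | None = None
    threshold_grid: list[float] | None = None
    k_folds: int = 10
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_GRAPHS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.task not in {"interaction", "direction"}:
            raise ValueError(f"unknown task {self.task!r}")


def default_threshold_grid(
    coords, n_points: int = 5, lo_pct: float = 1.0, hi_pct: float = 10.0,
    max_pairs: int = 200_000, seed: int = 0,
) -> list[float]:
    """Geometric grid spanning the 1st-10th percentile of pairwise distances.

    Distances are measured within fields of view; for large datasets a
    seeded subsample of pairs is used.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    dists = []
    for fov in pd.unique(coords.fov):
        idx = np.flatnonzero(coords.fov == fov)
        if len(idx) < 2:
            continue
        pts = np.column_stack([coords.x[idx], coords.y[idx]])
        m = len(idx)
        n_pairs = m * (m - 1) // 2
        if n_pairs > max_pairs:
            i = rng.integers(m, size=max_pairs)
            j = rng.integers(m, size=max_pairs)
            keep = i != j
            d = np.linalg.norm(pts[i[keep]] - pts[j[keep]], axis=1)
        else:
            from scipy.spatial.distance import pdist

            d = pdist(pts)
        dists.append(d)
    if not dists:
        raise ValueError("no field of view holds two cells")
    d = np.concatenate(dists)
    lo, hi = np.percentile(d, [lo_pct, hi_pct])
    lo = max(lo, 1e-9)
    return list(np.geomspace(lo, hi, n_points))


def select_threshold(grid: Sequence[float], validation_results: dict[float, float]) -> float:
    """The threshold with the best validation score; ties -> smallest."""
    if not grid:
        raise ValueError("empty threshold grid")
    scored = [(t, validation_results[t]) for t in grid if t in validation_results
              and np.isfinite(validation_results[t])]
    if not scored:
        raise ValueError("no threshold candidate produced a validation score")
    best_score = max(s for _, s in scored)
    return min(t for t, s in scored if s == best_score)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _direction_fold(fold: FoldPlan, seed: int) -> FoldPlan:
    """Recast an interaction fold as a direction fold.

    Each positive (L, R) on either side becomes the couple
    {(L, R, 1), (R, L, 0)}; negatives sampled for the interaction task are
    discarded.  Validation keeps whole couples so it stays balanced.
    """
    rng = np.random.default_rng(seed)

    def positives(samples):
        return [(s.gene_a, s.gene_b) for s in samples if s.label == 1]

    train_pos = positives(fold.train_samples) + positives(fold.validation_samples)
    test_pos = positives(fold.test_samples)
    train_all = direction_pairs(train_pos) if train_pos else []
    test_all = direction_pairs(test_pos) if test_pos else []
    n_couples = len(train_pos)
    v_couples = max(1, _round_half_up(0.2 * n_couples)) if n_couples else 0
    order = rng.permutation(n_couples)
    val_idx = set(order[:v_couples])
    val, tr = [], []
    for c in range(n_couples):
        couple = train_all[2 * c : 2 * c + 2]
        (val if c in val_idx else tr).extend(couple)
    return FoldPlan(
        fold_id=fold.fold_id,
        train_ligands=fold.train_ligands,
        test_ligands=fold.test_ligands,
        train_receptors=fold.train_receptors,
        test_receptors=fold.test_receptors,
        train_samples=tr,
        test_samples=test_all,
        validation_samples=val,
    )


def _run_folds(
    folds: Sequence[FoldPlan],
    graph,
    expr: ExpressionMatrix,
    cfg: ExperimentConfig,
    outdir: Path | None,
) -> EvalReport:
    reports = []
    rng = np.random.default_rng(cfg.seed)
    for fold in folds:
        fold_seed = int(rng.integers(2**31))
        if not fold.train_samples or not fold.test_samples:
            logger.warning("skipping fold %d (empty train or test)", fold.fold_id)
            continue
        fold.audit()
        tcfg = TrainConfig(**{**asdict(cfg.train), "seed": fold_seed,
                              "graph_variant": VARIANT_GRAPHS[cfg.variant]})
        t0 = time.time()
        params, log = train(fold, graph, expr, tcfg)
        probs = predict(params, graph, fold.test_samples, expr)
        report = per_ligand_curves(fold.test_samples, probs)
        logger.info(
            "fold %d: %d train / %d test samples, mean AUROC %.3f (%.1fs)",
            fold.fold_id, len(fold.train_samples), len(fold.test_samples),
            report.mean_auroc, time.time() - t0,
        )
        if outdir is not None:
            save_checkpoint(
                params,
                outdir / f"fold{fold.fold_id}.npz",
                meta={
                    "fold": fold.fold_id,
                    "seed": fold_seed,
                    "graph_variant": VARIANT_GRAPHS[cfg.variant],
                    "best_epoch": log[-1]["best_epoch"],
                    "best_val_accuracy": log[-1]["best_val_accuracy"],
                },
            )
            report.to_json(outdir / f"fold{fold.fold_id}_report.json")
        reports.append(report)
    if not reports:
        raise RuntimeError("all folds were skipped; no report to aggregate")
    return merge_reports(reports)


def _fold_plan_summary(folds: Sequence[FoldPlan]) -> list[dict]:
    return [
        {
            "fold": f.fold_id,
            "train_ligands": sorted(f.train_ligands),
            "test_ligands": sorted(f.test_ligands),
            "n_train": len(f.train_samples),
            "n_val": len(f.validation_samples),
            "n_test": len(f.test_samples),
        }
        for f in folds
    ]


def run_experiment(
    dataset: SimulatedDataset,
    cfg: ExperimentConfig,
    interactions: InteractionList | None = None,
    adjacency: AdjacencyMatrix | None = None,
) -> EvalReport:
    """Execute the configured task end to end and return the pooled report.

    ``interactions`` defaults to the dataset's true positive pairs;
    ``adjacency`` defaults to the graph at ``cfg.threshold`` (or the
    dataset's generating radius when no threshold is given).
    """
    expr = dataset.expression()
    if interactions is None:
        interactions = InteractionList(pairs=list(dataset.truth.positive_pairs))
    if adjacency is None:
        threshold = cfg.threshold if cfg.threshold is not None else dataset.config.radius
        adjacency = compute_adjacency(dataset.coords, threshold)
    graph = graph_matrix(adjacency, VARIANT_GRAPHS[cfg.variant])

    folds = make_folds(interactions, k=cfg.k_folds, seed=cfg.seed, task="interaction")
    if cfg.task == "direction":
        dir_rng = np.random.default_rng(cfg.seed + 1)
        folds = [_direction_fold(f, int(dir_rng.integers(2**31))) for f in folds]

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "fold_plans.json").write_text(
            json.dumps(_fold_plan_summary(folds), indent=2)
        )
    report = _run_folds(folds, graph, expr, cfg, outdir)
    if outdir is not None:
        report.to_json(outdir / "report.json")
        manifest = {
            "package_version": _pkg_version,
            "config": {**asdict(cfg), "train": asdict(cfg.train)},
            "threshold": adjacency.threshold,
            "n_cells": expr.n_cells,
            "n_genes": expr.n_genes,
            "n_interactions": len(interactions),
            "mean_auroc": report.mean_auroc,
            "mean_auprc": report.mean_auprc,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def run_permutation_control(
    kind: str,
    dataset: SimulatedDataset,
    cfg: ExperimentConfig,
    seed: int | None = None,
) -> EvalReport:
    """Re-run the pipeline with shuffled neighborhoods or shuffled labels.

    ``kind='graph'`` permutes the cell-to-coordinate assignment before the
    graph operator is built; ``kind='labels'`` permutes the
    ligand-receptor list before folds are made.  The returned report is
    tagged with the control kind.
    """
    if kind not in {"graph", "labels"}:
        raise ValueError("kind must be 'graph' or 'labels'")
    seed = cfg.seed if seed is None else seed
    interactions = InteractionList(pairs=list(dataset.truth.positive_pairs))
    threshold = cfg.threshold if cfg.threshold is not None else dataset.config.radius
    adjacency = compute_adjacency(dataset.coords, threshold)
    if kind == "graph":
        adjacency = permute_graph(adjacency, seed)
    else:
        interactions = permute_interactions(interactions, seed)
    report = run_experiment(dataset, cfg, interactions=interactions, adjacency=adjacency)
    report.control = kind
    return report


def tune_threshold(
    dataset: SimulatedDataset,
    grid: Sequence[float],
    cfg: ExperimentConfig,
    max_folds: int | None = None,
) -> tuple[float, dict[float, float]]:
    """Pick the neighborhood distance threshold on the validation split.

    For each candidate, one model per fold is trained on that candidate's
    graph and scored by AUROC on the fold's validation pairs; candidates
    are ranked by mean validation AUROC and the best (ties -> smallest)
    wins.  ``max_folds`` caps how many folds vote.
    """
    from sklearn.metrics import roc_auc_score

    expr = dataset.expression()
    interactions = InteractionList(pairs=list(dataset.truth.positive_pairs))
    folds = [
        f
        for f in make_folds(interactions, k=cfg.k_folds, seed=cfg.seed)
        if f.train_samples and f.validation_samples
    ]
    if max_folds is not None:
        folds = folds[:max_folds]
    if not folds:
        raise ValueError("no fold has both training and validation pairs")
    results: dict[float, float] = {}
    for t in grid:
        adjacency = compute_adjacency(dataset.coords, t)
        graph = graph_matrix(adjacency, VARIANT_GRAPHS[cfg.variant])
        scores = []
        for fold in folds:
            tcfg = TrainConfig(**{**asdict(cfg.train),
                                  "seed": cfg.seed + fold.fold_id,
                                  "graph_variant": VARIANT_GRAPHS[cfg.variant]})
            try:
                params, _ = train(fold, graph, expr, tcfg)
                probs = predict(params, graph, fold.validation_samples, expr)
                y = [s.label for s in fold.validation_samples]
                scores.append(float(roc_auc_score(y, probs)))
            except (RuntimeError, ValueError) as exc:
                logger.warning("threshold %.3g failed on fold %d: %s",
                               t, fold.fold_id, exc)
        results[t] = float(np.mean(scores)) if scores else float("nan")
    return select_threshold(list(grid), results), results


def run_function_task(
    expr: ExpressionMatrix,
    function_genes: Sequence[str],
    background: Sequence[str],
    cfg: ExperimentConfig,
    adjacency: AdjacencyMatrix,
    k: int = 5,
) -> EvalReport:
    """Function-assignment task with gene-level five-fold separation.

    Function genes and background genes are each partitioned into k
    chunks; fold i tests on chunk i of both and trains on the rest, so no
    gene appears on both sides.  Within each side, positives are
    within-function pairs and negatives pair a function gene with a
    background gene, 1:1.
    """
    rng = np.random.default_rng(cfg.seed)
    fn = np.array(sorted(set(map(str, function_genes))), dtype=object)
    bg = np.array(sorted(set(map(str, background)) - set(fn)), dtype=object)
    if len(fn) < 2 * k:
        raise ValueError("too few function genes for the requested fold count")
    rng.shuffle(fn)
    rng.shuffle(bg)
    fn_chunks = np.array_split(fn, k)
    bg_chunks = np.array_split(bg, k)
    graph = graph_matrix(adjacency, VARIANT_GRAPHS[cfg.variant])

    folds = []
    for i in range(k):
        test_fn, test_bg = set(fn_chunks[i]), set(bg_chunks[i])
        train_fn = set(fn) - test_fn
        train_bg = set(bg) - test_bg
        tr = function_pairs(train_fn, train_bg, seed=int(rng.integers(2**31)))
        te = function_pairs(test_fn, test_bg, seed=int(rng.integers(2**31)))
        n_val = max(2, _round_half_up(0.2 * len(tr)))
        perm = rng.permutation(len(tr))
        val = [tr[j] for j in perm[:n_val]]
        tr_rest = [tr[j] for j in perm[n_val:]]
        folds.append(
            FoldPlan(
                fold_id=i,
                train_ligands=train_fn,
                test_ligands=test_fn,
                train_receptors=train_bg,
                test_receptors=test_bg,
                train_samples=tr_rest,
                test_samples=te,
                validation_samples=val,
            )
        )
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    reports = []
    for fold in folds:
        if not fold.train_samples or not fold.test_samples:
            continue
        tcfg = TrainConfig(**{**asdict(cfg.train), "seed": int(rng.integers(2**31)),
                              "graph_variant": VARIANT_GRAPHS[cfg.variant]})
        params, _ = train(fold, graph, expr, tcfg)
        probs = predict(params, graph, fold.test_samples, expr)
        reports.append(per_ligand_curves(fold.test_samples, probs))
    return merge_reports(reports)
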