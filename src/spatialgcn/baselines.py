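"""Correlation baselines and guilt-by-association scoring.

Three non-neural comparison methods:

* single-cell Pearson correlation between the two genes of a pair across
  cells (no spatial information);
* spatial Pearson correlation: for a pair (a, b), the correlation between
  a's expression in each cell and the mean of b's expression over that
  cell's neighbors, symmetrized as the maximum over the two directions
  (the neighbor-mean construction is this package's operational choice);
* guilt-by-association (GBA): a candidate gene's score for a function is
  the sum of its single-cell correlations with the genes already known to
  have that function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .graph import AdjacencyMatrix

__all__ = [
    "ScoreTable",
    "single_cell_pc",
    "spatial_pc",
    "gba_score",
    "top_fraction_hits",
]


@dataclass
class ScoreTable:
    """Per-pair scores for one method, with degenerate-pair flags."""

    table: pd.DataFrame  # columns: gene_a, gene_b, score, method, degenerate

    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r with the zero-variance convention: score 0, flagged."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, True
    r = stats.pearsonr(x, y).statistic
    return float(r), False


def single_cell_pc(
    expr: ExpressionMatrix, pairs: Iterable[tuple[str, str]]
) -> ScoreTable:
    """Pearson correlation of the two genes' expression across cells."""
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells for a correlation")
    rows = []
    for a, b in pairs:
        r, degenerate = _pearson(expr.expression(a), expr.expression(b))
        rows.append((a, b, r, "single_cell_pc", degenerate))
    return ScoreTable(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "method", "degenerate"])
    )


def _neighbor_mean(A: AdjacencyMatrix, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    deg = A.degrees()
    has = deg > 0
    sums = np.asarray(A.A @ values).ravel()
    means = np.zeros_like(sums)
    means[has] = sums[has] / deg[has]
    return means, has


def spatial_pc(
    expr: ExpressionMatrix,
    A: AdjacencyMatrix,
    pairs: Iterable[tuple[str, str]],
) -> ScoreTable:
    """Correlation between a gene and its partner's neighborhood average.

    For direction a->b: r( a_i , mean_{j in N(i)} b_j ) over cells with at
    least one neighbor; the reported score is the maximum over both
    directions so it is invariant to pair order.
    """
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if A.n != expr.n_cells:
        raise ValueError("graph and expression matrix are misaligned")
    deg = A.degrees()
    if not (deg > 0).any():
        raise ValueError("no cell has a neighbor; graph is empty")
    rows = []
    for a, b in pairs:
        xa, xb = expr.expression(a), expr.expression(b)
        scores, flags = [], []
        for src, dst in ((xa, xb), (xb, xa)):
            means, has = _neighbor_mean(A, dst)
            r, degenerate = _pearson(src[has], means[has])
            scores.append(r)
            flags.append(degenerate)
        rows.append((a, b, max(scores), "spatial_pc", all(flags)))
    return ScoreTable(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "method", "degenerate"])
    )


def gba_score(
    expr: ExpressionMatrix, candidate: str, known: Iterable[str]
) -> float:
    """Summed single-cell correlation of the candidate with the known set."""
    known = sorted(set(known))
    if not known:
        raise ValueError("known gene set is empty")
    if candidate in known:
        raise ValueError("candidate gene must not be in the known set")
    x = expr.expression(candidate)
    total = 0.0
    for g in known:
        r, _ = _pearson(x, expr.expression(g))
        total += r
    return float(total)


def top_fraction_hits(
    scores: ScoreTable | Sequence[float],
    candidates: Sequence[str] | None = None,
    truth: Iterable[str] = (),
    fraction: float = 0.2,
) -> float:
    """Precision within the top-scoring fraction of candidates.

    Candidates are ranked by score (descending), ties broken by candidate
    id for determinism; the top ceil(fraction * N) are taken and the
    returned value is the fraction of them that belong to ``truth``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(scores, ScoreTable):
        if candidates is None:
            candidates = scores.table["gene_a"].astype(str).tolist()
        values = scores.scores()
    else:
        values = np.asarray(scores, dtype=float)
        if candidates is None:
            raise ValueError("candidates required when scores is a plain sequence")
    candidates = [str(c) for c in candidates]
    if len(candidates) == 0:
        raise ValueError("no candidates to rank")
    if len(candidates) != len(values):
        raise ValueError("candidates and scores differ in length")
    truth = set(map(str, truth))
    order = sorted(range(len(candidates)), key=lambda i: (-values[i], candidates[i]))
    k = int(np.ceil(fraction * len(candidates)))
    top = order[:k]
    return float(sum(candidates[i] in truth for i in top) / k)
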