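"""Count matrices, per-cell normalization, and per-pair node features.

Counts are scaled per cell so that every cell's total normalized expression
is 10,000:

    expression_ij = count_ij / sum_j count_ij * 10,000

All-zero cells are left as zeros (with a logged warning) rather than being
dropped, so the expression rows stay aligned with the cell graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "TOTAL_PER_CELL",
    "ExpressionMatrix",
    "PairFeatures",
    "normalize_counts",
    "pair_features",
    "highly_expressing_cells",
    "read_counts",
    "write_counts",
]

TOTAL_PER_CELL = 10_000.0


@dataclass
class ExpressionMatrix:
    """Raw and per-cell-normalized counts with gene/cell indices.

    ``counts`` and ``normalized`` are cells x genes; rows align with
    ``cell_ids`` and columns with ``gene_ids``.
    """

    counts: np.ndarray
    normalized: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != self.normalized.shape:
            raise ValueError("counts and normalized shapes disagree")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match id lengths")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        """Locate a gene id; exact match preferred, else case-insensitive."""
        hits = np.flatnonzero(self.gene_ids == gene)
        if len(hits) == 0:
            lowered = np.char.lower(self.gene_ids.astype(str))
            hits = np.flatnonzero(lowered == str(gene).lower())
        if len(hits) == 0:
            raise KeyError(f"gene {gene!r} not present in expression matrix")
        return int(hits[0])

    def has_gene(self, gene: str) -> bool:
        try:
            self.gene_index(gene)
            return True
        except KeyError:
            return False

    def expression(self, gene: str) -> np.ndarray:
        return self.normalized[:, self.gene_index(gene)]


@dataclass
class PairFeatures:
    """The n x 2 node-feature matrix for one ordered gene pair.

    Column 0 holds gene_a, column 1 gene_b, with rows in the cell order of
    the graph the features will be convolved over.
    """

    X: np.ndarray
    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError("pair features must be n x 2")


def normalize_counts(
    counts: np.ndarray | sp.spmatrix,
    gene_ids: Sequence[str] | None = None,
    cell_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Scale each cell's counts to sum to 10,000.

    All-zero cells remain all-zero; their count is logged as a warning so a
    pipeline can notice without losing graph/expression index alignment.
    """
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (cells x genes)")
    if not np.isfinite(counts).all():
        raise ValueError("counts contain non-finite values")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero cell(s) left unnormalized", int(zero.sum()))
    scale = np.zeros_like(totals)
    scale[~zero] = TOTAL_PER_CELL / totals[~zero]
    normalized = counts * scale[:, None]
    n_cells, n_genes = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(n_cells)]
    return ExpressionMatrix(
        counts=counts,
        normalized=normalized,
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
    )


def pair_features(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    cell_order: Sequence[str] | None = None,
) -> PairFeatures:
    """Assemble the n x 2 feature matrix for an ordered gene pair.

    ``cell_order`` must be a permutation of the matrix's cell ids (the graph
    order); by default the matrix's own order is used.
    """
    a = expr.expression(gene_a)
    b = expr.expression(gene_b)
    if cell_order is not None:
        order = np.asarray(cell_order, dtype=object)
        pos = {c: i for i, c in enumerate(expr.cell_ids)}
        try:
            idx = np.array([pos[c] for c in order])
        except KeyError as exc:
            raise ValueError(f"cell {exc.args[0]!r} not in expression matrix") from None
        if len(idx) != expr.n_cells or len(set(order)) != len(order):
            raise ValueError("cell_order is not a permutation of the cell ids")
        a, b = a[idx], b[idx]
    return PairFeatures(X=np.column_stack([a, b]), gene_a=gene_a, gene_b=gene_b)


def highly_expressing_cells(
    expr: ExpressionMatrix, gene: str, k: int = 100
) -> list[str]:
    """The k cells with highest normalized expression of ``gene``.

    Returns all cells when fewer than k exist.  Ties at the boundary are
    broken by lexicographic cell id, so the selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    values = expr.expression(gene)
    ids = expr.cell_ids.astype(str)
    # sort by (-expression, cell_id): highest first, lexicographic tie-break
    order = np.lexsort((ids, -values))
    chosen = order[: min(k, expr.n_cells)]
    return [str(ids[i]) for i in chosen]


def _looks_like_genes_by_cells(df: pd.DataFrame) -> bool:
    # heuristics: more rows than columns usually means genes x cells in
    # imaging data (thousands of genes, hundreds-to-thousands of cells is
    # ambiguous, so wide matrices fall back to cells x genes)
    return df.shape[0] > df.shape[1]


def read_counts(
    path: str | Path,
    orientation: str = "auto",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a count matrix and normalize it.

    TSV/CSV files must carry gene and cell headers (first column = row
    index).  Matrix-Market triplets need sidecar ``genes.tsv`` /
    ``cells.tsv`` files (rows = genes, columns = cells, the MTX convention
    used by expression pipelines).  ``orientation`` is one of ``auto``,
    ``cells_by_genes``, ``genes_by_cells``.
    """
    path = Path(path)
    if orientation not in {"auto", "cells_by_genes", "genes_by_cells"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if path.suffix.lower() == ".mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "cells.tsv"
        M = np.asarray(sp.csr_matrix(mmread(str(path))).todense())
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
        if M.shape == (len(genes), len(cells)):
            M = M.T
        elif M.shape != (len(cells), len(genes)):
            raise ValueError("MTX shape matches neither genes x cells nor cells x genes")
        return normalize_counts(M, gene_ids=genes, cell_ids=cells)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_by_cells" or (
        orientation == "auto" and _looks_like_genes_by_cells(df)
    ):
        df = df.T
    return normalize_counts(
        df.to_numpy(dtype=float),
        gene_ids=df.columns.astype(str),
        cell_ids=df.index.astype(str),
    )


def write_counts(expr: ExpressionMatrix, directory: str | Path) -> dict[str, Path]:
    """Write raw counts as MTX (genes x cells) with gene/cell sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "counts.mtx"
    genes = directory / "genes.tsv"
    cells = directory / "cells.tsv"
    mmwrite(str(mtx), sp.coo_matrix(expr.counts.T), field="integer"
            if np.allclose(expr.counts, np.round(expr.counts)) else "real")
    pd.Series(expr.gene_ids).to_csv(genes, sep="\t", index=False, header=False)
    pd.Series(expr.cell_ids).to_csv(cells, sep="\t", index=False, header=False)
    return {"matrix": mtx, "genes": genes, "cells": cells}
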