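"""Cell neighborhood graphs and their normalized matrix variants.

Cells imaged in situ come with 2-D coordinates inside one or more fields of
view (FOVs).  Two cells are declared neighbors when their Euclidean distance
in image units is at most a threshold; coordinates from different FOVs live
in unrelated frames, so edges never cross FOV boundaries.  From the binary
adjacency ``A`` this module derives every graph operator used by the
classifier:

``L_N``
    symmetric normalized Laplacian ``I - D^{-1/2} A D^{-1/2}``.
``A_N``
    symmetrically normalized adjacency ``D^{-1/2} A D^{-1/2}``.
``L_NN``
    the normalized Laplacian of ``A_N`` itself (two-stage normalization,
    applied verbatim: degrees are recomputed from ``A_N``).
``L_prime``
    self-loop renormalization ``D'^{-1/2} (A + I) D'^{-1/2}``.
``diagonal``
    the identity — a graph-free control in which every cell sees only
    itself.

Zero-degree convention: ``(D^{-1/2})_ii = 0`` whenever ``D_ii = 0``, so an
isolated cell contributes a 1 on the diagonal of the Laplacian variants and
nothing to ``A_N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.spatial import cKDTree

__all__ = [
    "CellCoordinates",
    "AdjacencyMatrix",
    "GraphMatrix",
    "compute_adjacency",
    "degree_matrix",
    "normalized_laplacian",
    "normalize_adjacency",
    "double_normalized_laplacian",
    "self_loop_normalized",
    "diagonal_graph",
    "permute_graph",
    "graph_matrix",
    "read_coordinates",
    "write_graph",
    "read_graph",
]

GRAPH_VARIANTS = ("L_N", "A_N", "L_NN", "L_prime", "diagonal")

# dense linear algebra is cheaper than sparse below this cell count
_DENSE_LIMIT = 2000


@dataclass
class CellCoordinates:
    """Per-cell 2-D positions with a field-of-view label.

    ``cell_id`` entries must be unique and coordinates finite; every cell
    carries an ``fov`` label (single-FOV datasets use one label throughout).
    """

    cell_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fov: np.ndarray

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.fov = np.asarray(self.fov, dtype=object)
        n = len(self.cell_id)
        if not (len(self.x) == len(self.y) == len(self.fov) == n):
            raise ValueError("coordinate columns have mismatched lengths")
        if len(set(self.cell_id)) != n:
            raise ValueError("duplicate cell_id in coordinates")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite coordinate")

    def __len__(self) -> int:
        return len(self.cell_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellCoordinates":
        required = {"cell_id", "x", "y", "fov"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
        return cls(
            cell_id=df["cell_id"].astype(str).to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            fov=df["fov"].astype(str).to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "x": self.x, "y": self.y, "fov": self.fov}
        )


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal cell adjacency with its threshold."""

    A: sp.csr_matrix
    cell_ids: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()


@dataclass
class GraphMatrix:
    """One of the graph operators fed to the classifier."""

    M: np.ndarray
    variant: str
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variant not in GRAPH_VARIANTS:
            raise ValueError(f"unknown graph variant {self.variant!r}")
        if sp.issparse(self.M):
            if self.M.shape[0] <= _DENSE_LIMIT:
                self.M = np.asarray(self.M.todense())
            else:
                self.M = sp.csr_matrix(self.M)
        else:
            self.M = np.asarray(self.M, dtype=float)
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.shape[0]).astype(object)

    @property
    def shape(self):
        return self.M.shape

    def dense(self) -> np.ndarray:
        return self.M.toarray() if sp.issparse(self.M) else np.asarray(self.M)

    def matmul(self, X: np.ndarray) -> np.ndarray:
        """Apply the operator to stacked node features of shape (n, ...)."""
        if X.ndim == 2:
            return self.M @ X
        n = X.shape[0]
        flat = X.reshape(n, -1)
        return np.asarray(self.M @ flat).reshape(X.shape)


def compute_adjacency(coords: CellCoordinates, threshold: float) -> AdjacencyMatrix:
    """Neighborhood adjacency: cells within ``threshold`` of each other,
    restricted to the same field of view.

    ``A_ij = A_ji = 1`` iff ``i != j``, both cells share an FOV, and their
    Euclidean distance is at most ``threshold``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    n = len(coords)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for fov in pd.unique(coords.fov):
        idx = np.flatnonzero(coords.fov == fov)
        if len(idx) < 2 or threshold == 0:
            continue
        pts = np.column_stack([coords.x[idx], coords.y[idx]])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=threshold, output_type="ndarray")
        if len(pairs):
            rows.append(idx[pairs[:, 0]])
            cols.append(idx[pairs[:, 1]])
    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        data = np.ones(2 * len(i))
        A = sp.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
        A.data[:] = 1.0  # collapse any duplicate entries
    else:
        A = sp.csr_matrix((n, n))
    return AdjacencyMatrix(A=A, cell_ids=coords.cell_id, threshold=float(threshold))


def degree_matrix(adj: AdjacencyMatrix) -> np.ndarray:
    """Diagonal degree matrix D with D_ii = sum_j A_ij, returned dense."""
    return np.diag(adj.degrees())


def _inv_sqrt(deg: np.ndarray) -> np.ndarray:
    """Entrywise d^{-1/2} with the zero-degree convention d=0 -> 0."""
    out = np.zeros_like(deg, dtype=float)
    nz = deg > 0
    out[nz] = 1.0 / np.sqrt(deg[nz])
    return out


def _sym_normalize(A: sp.spmatrix, deg: np.ndarray) -> sp.csr_matrix:
    d = _inv_sqrt(deg)
    Dinv = sp.diags(d)
    return sp.csr_matrix(Dinv @ A @ Dinv)


def normalize_adjacency(adj: AdjacencyMatrix) -> GraphMatrix:
    """A_N = D^{-1/2} A D^{-1/2} (symmetric, nonnegative)."""
    An = _sym_normalize(adj.A, adj.degrees())
    return GraphMatrix(M=An, variant="A_N", cell_ids=adj.cell_ids)


def normalized_laplacian(adj: AdjacencyMatrix) -> GraphMatrix:
    """L_N = I - D^{-1/2} A D^{-1/2}."""
    An = _sym_normalize(adj.A, adj.degrees())
    L = sp.identity(adj.n, format="csr") - An
    return GraphMatrix(M=L, variant="L_N", cell_ids=adj.cell_ids)


def double_normalized_laplacian(adj: AdjacencyMatrix) -> GraphMatrix:
    """L_NN = I - D_N^{-1/2} A_N D_N^{-1/2}, with D_N the degrees of A_N.

    The already-normalized adjacency is normalized a second time before the
    Laplacian is formed; degrees are recomputed from A_N, not reused.
    """
    An = _sym_normalize(adj.A, adj.degrees())
    deg_n = np.asarray(An.sum(axis=1)).ravel()
    Ann = _sym_normalize(An, deg_n)
    L = sp.identity(adj.n, format="csr") - Ann
    return GraphMatrix(M=L, variant="L_NN", cell_ids=adj.cell_ids)


def self_loop_normalized(adj: AdjacencyMatrix) -> GraphMatrix:
    """L' = D'^{-1/2} A' D'^{-1/2} with A' = A + I.

    The self-loop keeps each cell's own expression in its embedding, which
    is what lets the model capture autocrine (same-cell) signaling.
    """
    Ap = sp.csr_matrix(adj.A + sp.identity(adj.n, format="csr"))
    deg = np.asarray(Ap.sum(axis=1)).ravel()
    Lp = _sym_normalize(Ap, deg)
    return GraphMatrix(M=Lp, variant="L_prime", cell_ids=adj.cell_ids)


def diagonal_graph(n: int, cell_ids: Sequence | None = None) -> GraphMatrix:
    """Identity operator: the graph-free (autocrine-only) control."""
    if n <= 0:
        raise ValueError("n must be positive")
    ids = np.asarray(cell_ids, dtype=object) if cell_ids is not None else None
    return GraphMatrix(M=np.eye(n), variant="diagonal", cell_ids=ids)


def graph_matrix(adj: AdjacencyMatrix, variant: str) -> GraphMatrix:
    """Dispatch on variant name; 'diagonal' ignores the edges entirely."""
    builders = {
        "L_N": normalized_laplacian,
        "A_N": normalize_adjacency,
        "L_NN": double_normalized_laplacian,
        "L_prime": self_loop_normalized,
    }
    if variant == "diagonal":
        return diagonal_graph(adj.n, adj.cell_ids)
    if variant not in builders:
        raise ValueError(f"unknown graph variant {variant!r}")
    return builders[variant](adj)


def permute_graph(adj: AdjacencyMatrix, seed: int) -> AdjacencyMatrix:
    """Permutation control: randomly reassign cells to coordinates.

    Implemented as a simultaneous row/column permutation of A, which
    preserves the degree multiset while destroying the true neighborhood
    of every cell.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(adj.n)
    P = sp.csr_matrix(
        (np.ones(adj.n), (perm, np.arange(adj.n))), shape=(adj.n, adj.n)
    )
    A = sp.csr_matrix(P @ adj.A @ P.T)
    return AdjacencyMatrix(A=A, cell_ids=adj.cell_ids, threshold=adj.threshold)


def read_coordinates(path: str | Path) -> CellCoordinates:
    """Read a cell coordinate table (TSV or CSV) with columns
    cell_id, x, y, fov."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return CellCoordinates.from_frame(pd.read_csv(path, sep=sep))


def write_graph(adj: AdjacencyMatrix, directory: str | Path) -> dict[str, Path]:
    """Export the adjacency as Matrix-Market triplets plus a cell index TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "adjacency.mtx"
    idx = directory / "cells.tsv"
    mmwrite(str(mtx), sp.coo_matrix(adj.A))
    pd.DataFrame({"cell_id": adj.cell_ids}).to_csv(idx, sep="\t", index=False)
    (directory / "threshold.txt").write_text(f"{adj.threshold}\n")
    return {"matrix": mtx, "cells": idx}


def read_graph(directory: str | Path) -> AdjacencyMatrix:
    directory = Path(directory)
    A = sp.csr_matrix(mmread(str(directory / "adjacency.mtx")))
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")["cell_id"].astype(str)
    thr_file = directory / "threshold.txt"
    threshold = float(thr_file.read_text().strip()) if thr_file.exists() else float("nan")
    return AdjacencyMatrix(A=A, cell_ids=cells.to_numpy(), threshold=threshold)
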