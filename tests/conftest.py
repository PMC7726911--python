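import numpy as np
import pytest

from spatialgcn.expression import normalize_counts
from spatialgcn.graph import AdjacencyMatrix, CellCoordinates
from spatialgcn.labels import InteractionList
from spatialgcn.simulate import SimConfig, simulate
import scipy.sparse as sp


@pytest.fixture
def path3_adjacency():
    """Path graph 1-2-3."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return AdjacencyMatrix(A=sp.csr_matrix(A), cell_ids=np.array(["a", "b", "c"]),
                           threshold=1.0)


@pytest.fixture
def two_node_adjacency():
    A = np.array([[0, 1], [1, 0]], dtype=float)
    return AdjacencyMatrix(A=sp.csr_matrix(A), cell_ids=np.array(["a", "b"]),
                           threshold=1.0)


@pytest.fixture
def small_expression():
    """3 cells x 3 genes with easy normalized values."""
    counts = np.array([[1, 1, 2], [10, 0, 0], [0, 0, 0]], dtype=float)
    return normalize_counts(counts, gene_ids=["gA", "gB", "gC"],
                            cell_ids=["c1", "c2", "c3"])


@pytest.fixture
def toy_interactions():
    return InteractionList(
        pairs=[(f"L{i}", f"R{i}") for i in range(20)]
    )


def tiny_sim_config(seed=0, **overrides):
    """Small, fast simulation used across tests."""
    base = dict(
        n_cells=150,
        n_fov=2,
        arena=1000.0,
        radius=100.0,
        n_genes=60,
        n_pos_pairs=10,
        coupling_mode="exocrine",
        coupling_strength=1.0,
        noise_dispersion=1.0,
        bump_sigma_frac=0.06,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def tiny_dataset():
    return simulate(tiny_sim_config(seed=3))
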