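"""Neighborhood graph construction and normalized matrix variants."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from spatialgcn.graph import (
    AdjacencyMatrix,
    CellCoordinates,
    compute_adjacency,
    degree_matrix,
    diagonal_graph,
    double_normalized_laplacian,
    graph_matrix,
    normalize_adjacency,
    normalized_laplacian,
    permute_graph,
    read_graph,
    self_loop_normalized,
    write_graph,
)


def coords(points, fovs=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return CellCoordinates(
        cell_id=np.array([f"c{i}" for i in range(n)]),
        x=points[:, 0],
        y=points[:, 1],
        fov=np.array(fovs if fovs is not None else ["f"] * n),
    )


def dense_variant_oracle(A, variant):
    """Independent dense computation of every matrix variant."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]

    def inv_sqrt_diag(M):
        d = M.sum(axis=1)
        out = np.zeros(n)
        out[d > 0] = d[d > 0] ** -0.5
        return np.diag(out)

    if variant == "A_N":
        D = inv_sqrt_diag(A)
        return D @ A @ D
    if variant == "L_N":
        D = inv_sqrt_diag(A)
        return np.eye(n) - D @ A @ D
    if variant == "L_NN":
        D = inv_sqrt_diag(A)
        An = D @ A @ D
        Dn = inv_sqrt_diag(An)
        return np.eye(n) - Dn @ An @ Dn
    if variant == "L_prime":
        Ap = A + np.eye(n)
        Dp = inv_sqrt_diag(Ap)
        return Dp @ Ap @ Dp
    raise ValueError(variant)


class TestComputeAdjacency:
    def test_threshold_selects_close_pairs_only(self):
        c = coords([(0, 0), (1, 0), (5, 0)])
        A = compute_adjacency(c, 1.5).A.toarray()
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1
        np.testing.assert_array_equal(A, expected)

    def test_zero_threshold_gives_empty_graph(self):
        c = coords([(0, 0), (0, 0), (1, 1)])
        assert compute_adjacency(c, 0.0).A.nnz == 0

    def test_no_edges_across_fields_of_view(self):
        c = coords([(0, 0), (0, 0)], fovs=["1", "2"])
        assert compute_adjacency(c, 10.0).A.nnz == 0

    def test_duplicate_cell_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CellCoordinates(
                cell_id=np.array(["a", "a"]),
                x=np.array([0.0, 1.0]),
                y=np.array([0.0, 1.0]),
                fov=np.array(["f", "f"]),
            )

    def test_non_finite_coordinate_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            CellCoordinates(
                cell_id=np.array(["a", "b"]),
                x=np.array([0.0, np.nan]),
                y=np.array([0.0, 1.0]),
                fov=np.array(["f", "f"]),
            )

    def test_rigid_motions_preserve_adjacency(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 10, size=(30, 2))
        A0 = compute_adjacency(coords(pts), 2.0).A.toarray()
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([5.0, -3.0])
        A1 = compute_adjacency(coords(moved), 2.0).A.toarray()
        np.testing.assert_array_equal(A0, A1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_adjacency_symmetric_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 5, size=(12, 2))
        A = compute_adjacency(coords(pts), 1.0).A.toarray()
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert set(np.unique(A)) <= {0.0, 1.0}


class TestDegreeMatrix:
    @pytest.mark.parametrize(
        "A, expected",
        [
            ([[0, 1], [1, 0]], [1, 1]),
            ([[0, 0], [0, 0]], [0, 0]),
            ([[0, 1, 0], [1, 0, 1], [0, 1, 0]], [1, 2, 1]),
        ],
    )
    def test_row_sums(self, A, expected):
        adj = AdjacencyMatrix(A=sp.csr_matrix(np.array(A, dtype=float)),
                              cell_ids=np.arange(len(A)), threshold=1.0)
        np.testing.assert_array_equal(degree_matrix(adj), np.diag(expected))


class TestGraphVariants:
    def test_two_node_values_exact(self, two_node_adjacency):
        np.testing.assert_array_equal(
            normalized_laplacian(two_node_adjacency).dense(),
            [[1, -1], [-1, 1]],
        )
        np.testing.assert_array_equal(
            normalize_adjacency(two_node_adjacency).dense(), [[0, 1], [1, 0]]
        )
        np.testing.assert_array_equal(
            double_normalized_laplacian(two_node_adjacency).dense(),
            [[1, -1], [-1, 1]],
        )
        np.testing.assert_allclose(
            self_loop_normalized(two_node_adjacency).dense(),
            [[0.5, 0.5], [0.5, 0.5]],
        )

    def test_path3_against_dense_oracle(self, path3_adjacency):
        A = path3_adjacency.A.toarray()
        builders = {
            "L_N": normalized_laplacian,
            "A_N": normalize_adjacency,
            "L_NN": double_normalized_laplacian,
            "L_prime": self_loop_normalized,
        }
        for variant, build in builders.items():
            np.testing.assert_allclose(
                build(path3_adjacency).dense(),
                dense_variant_oracle(A, variant),
                atol=1e-9,
            )
        # hand values: L_N off-diagonals -1/sqrt(2); L' diag (1/2,1/3,1/2),
        # edges 1/sqrt(6)
        LN = normalized_laplacian(path3_adjacency).dense()
        assert LN[0, 1] == pytest.approx(-1 / np.sqrt(2))
        Lp = self_loop_normalized(path3_adjacency).dense()
        np.testing.assert_allclose(np.diag(Lp), [0.5, 1 / 3, 0.5])
        assert Lp[0, 1] == pytest.approx(1 / np.sqrt(6))

    @pytest.mark.parametrize("variant", ["L_N", "A_N", "L_NN", "L_prime"])
    def test_random_graphs_match_oracle_and_are_symmetric(self, variant):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = rng.integers(2, 20)
            A = (rng.random((n, n)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            adj = AdjacencyMatrix(A=sp.csr_matrix(A), cell_ids=np.arange(n),
                                  threshold=1.0)
            M = graph_matrix(adj, variant).dense()
            np.testing.assert_allclose(M, dense_variant_oracle(A, variant), atol=1e-9)
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            if variant in ("A_N", "L_prime"):
                assert (M >= -1e-12).all()

    @pytest.mark.parametrize(
        "variant, expected",
        [("L_N", np.eye(4)), ("A_N", np.zeros((4, 4))),
         ("L_NN", np.eye(4)), ("L_prime", np.eye(4))],
    )
    def test_empty_graph_limits(self, variant, expected):
        adj = AdjacencyMatrix(A=sp.csr_matrix((4, 4)), cell_ids=np.arange(4),
                              threshold=1.0)
        np.testing.assert_array_equal(graph_matrix(adj, variant).dense(), expected)

    def test_self_loop_complete_graph_uniform(self):
        n = 5
        A = np.ones((n, n)) - np.eye(n)
        adj = AdjacencyMatrix(A=sp.csr_matrix(A), cell_ids=np.arange(n),
                              threshold=1.0)
        np.testing.assert_allclose(
            self_loop_normalized(adj).dense(), np.full((n, n), 1 / n)
        )

    def test_normalized_adjacency_row_sums_brute_force(self):
        rng = np.random.default_rng(5)
        n = 15
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        A[A.sum(axis=1) == 0, 0] = 1  # avoid isolated nodes
        A[0, A[:, 0] == 1] = 1
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        adj = AdjacencyMatrix(A=sp.csr_matrix(A), cell_ids=np.arange(n),
                              threshold=1.0)
        An = normalize_adjacency(adj).dense()
        deg = A.sum(axis=1)
        expected = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if A[i, j]:
                    expected[i] += A[i, j] / np.sqrt(deg[i] * deg[j])
        np.testing.assert_allclose(An.sum(axis=1), expected, atol=1e-12)


class TestDiagonalGraph:
    def test_identity(self):
        np.testing.assert_array_equal(diagonal_graph(1).dense(), [[1.0]])
        np.testing.assert_array_equal(diagonal_graph(3).dense(), np.eye(3))

    def test_identity_action(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        np.testing.assert_array_equal(diagonal_graph(4).matmul(X), X)

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            diagonal_graph(0)


class TestPermuteGraph:
    def test_deterministic_and_degree_preserving(self, path3_adjacency):
        p1 = permute_graph(path3_adjacency, seed=4)
        p2 = permute_graph(path3_adjacency, seed=4)
        assert (p1.A != p2.A).nnz == 0
        assert sorted(p1.degrees()) == sorted(path3_adjacency.degrees())

    def test_stays_symmetric_binary(self):
        rng = np.random.default_rng(2)
        A = (rng.random((10, 10)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        adj = AdjacencyMatrix(A=sp.csr_matrix(A), cell_ids=np.arange(10),
                              threshold=1.0)
        P = permute_graph(adj, seed=1).A.toarray()
        np.testing.assert_array_equal(P, P.T)
        assert np.all(np.diag(P) == 0)


def test_graph_round_trip(tmp_path, path3_adjacency):
    write_graph(path3_adjacency, tmp_path)
    back = read_graph(tmp_path)
    assert (back.A != path3_adjacency.A).nnz == 0
    assert list(back.cell_ids) == list(path3_adjacency.cell_ids)
    assert back.threshold == path3_adjacency.threshold
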