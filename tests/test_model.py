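"""Forward pass, gradients, training loop, and prediction contracts."""

import numpy as np
import pytest
import scipy.sparse as sp

from spatialgcn.expression import normalize_counts
from spatialgcn.graph import GraphMatrix, diagonal_graph
from spatialgcn.labels import FoldPlan, PairSample
from spatialgcn.model import (
    ModelParams,
    TrainConfig,
    elu,
    forward,
    graph_conv,
    init_params,
    load_checkpoint,
    loss,
    predict,
    save_checkpoint,
    train,
)


def graph_conv_oracle(L, X, W, b, alpha=1.0):
    """Scalar triple-loop computation of elu(LXW + b)."""
    L, X, W, b = map(np.asarray, (L, X, W, b))
    n, f = X.shape[0], W.shape[1]
    out = np.zeros((n, f))
    for i in range(n):
        for m in range(f):
            acc = b[m]
            for k in range(n):
                for c in range(X.shape[1]):
                    acc += L[i, k] * X[k, c] * W[c, m]
            out[i, m] = acc if acc > 0 else alpha * (np.exp(acc) - 1)
    return out


def zero_params(n, channels=4, dense=6):
    return ModelParams(
        W1=np.zeros((2, channels)),
        b1=np.zeros(channels),
        W2=np.zeros((channels, channels)),
        b2=np.zeros(channels),
        W_dense=np.zeros((channels * n, dense)),
        b_dense=np.zeros(dense),
        w_out=np.zeros(dense),
        b_out=0.0,
    )


class TestGraphConv:
    def test_zero_operator_gives_zero_output(self):
        Z = graph_conv(np.zeros((3, 3)), np.ones((3, 2)), np.ones((2, 4)),
                       np.zeros(4))
        np.testing.assert_array_equal(Z, np.zeros((3, 4)))

    def test_elu_branches(self):
        L = np.eye(2)
        X = np.array([[2.0, 9.0], [-1.0, 9.0]])
        W = np.array([[1.0], [0.0]])
        Z = graph_conv(L, X, W, np.zeros(1))
        np.testing.assert_allclose(Z, [[2.0], [np.exp(-1) - 1]])

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, c, f = 10, 2, 3
            L = rng.normal(size=(n, n))
            X = rng.normal(size=(n, c)) * 3
            W = rng.normal(size=(c, f))
            b = rng.normal(size=f)
            np.testing.assert_allclose(
                graph_conv(L, X, W, b), graph_conv_oracle(L, X, W, b), atol=1e-6
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_conv(np.eye(3), np.ones((4, 2)), np.ones((2, 3)), np.zeros(3))
        with pytest.raises(ValueError):
            graph_conv(np.eye(3), np.ones((3, 2)), np.ones((3, 3)), np.zeros(3))


class TestForward:
    def test_all_zero_parameters_give_half(self):
        p = forward(np.eye(5), np.random.default_rng(0).normal(size=(5, 2)),
                    zero_params(5))
        assert p == pytest.approx(0.5)

    def test_probability_in_open_unit_interval(self):
        rng = np.random.default_rng(3)
        params = init_params(6, seed=1, channels=4, dense_units=5)
        for _ in range(5):
            p = forward(np.eye(6), rng.normal(size=(6, 2)) * 10, params)
            assert 0 < p < 1

    def test_equals_manual_layer_composition(self):
        rng = np.random.default_rng(4)
        n = 3
        L = rng.normal(size=(n, n))
        X = rng.normal(size=(n, 2))
        params = init_params(n, seed=2, channels=4, dense_units=5)
        z1 = graph_conv(L, X, params.W1, params.b1)
        z2 = graph_conv(L, z1, params.W2, params.b2)
        flat = np.maximum(z2.reshape(-1), 0)
        hidden = np.maximum(flat @ params.W_dense + params.b_dense, 0)
        logit = hidden @ params.w_out + params.b_out
        expected = 1 / (1 + np.exp(-logit))
        assert forward(L, X, params) == pytest.approx(expected, abs=1e-12)

    def test_conv_stack_permutation_equivariant(self):
        rng = np.random.default_rng(5)
        n = 8
        L = rng.normal(size=(n, n))
        X = rng.normal(size=(n, 2))
        params = init_params(n, seed=3, channels=4, dense_units=5)

        def stack(Lm, Xm):
            z1 = graph_conv(Lm, Xm, params.W1, params.b1)
            return graph_conv(Lm, z1, params.W2, params.b2)

        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        lhs = stack(P @ L @ P.T, P @ X)
        rhs = P @ stack(L, X)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_cell_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward(np.eye(4), np.ones((4, 2)), zero_params(5))


class TestLoss:
    def test_confident_correct_is_near_zero(self):
        assert loss([1], [1 - 1e-9]) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_prediction_is_ln_two(self):
        assert loss([1], [0.5]) == pytest.approx(np.log(2))

    def test_matches_scalar_hand_sum(self):
        y = [1, 0, 1]
        p = [0.9, 0.2, 0.8]
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.8))
        assert loss(y, p) == pytest.approx(expected)

    def test_out_of_range_probabilities_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            value = loss([1, 0], [1.0, 0.0])
        assert np.isfinite(value)
        assert "clipped" in caplog.text


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        from spatialgcn.model import _backward, _batch_forward

        rng = np.random.default_rng(6)
        n, B = 6, 4
        L = rng.normal(size=(n, n)) * 0.5
        Xb = rng.normal(size=(B, n, 2))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        params = init_params(n, seed=4, channels=3, dense_units=4)

        def objective(p):
            probs = _batch_forward(L, Xb, p)
            probs = np.clip(probs, 1e-12, 1 - 1e-12)
            return float(-(y * np.log(probs) + (1 - y) * np.log(1 - probs)).mean())

        probs, cache = _batch_forward(L, Xb, params, cache=True)
        cache["p"] = probs
        grads, _ = _backward(L, Xb, y, params, cache)

        eps = 1e-6
        arrays = params.arrays()
        for name in ["W1", "b1", "W2", "b2", "W_dense", "b_dense", "w_out"]:
            arr = arrays[name]
            flat_idx = [0, arr.size // 2, arr.size - 1]
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                up = objective(params)
                arr[idx] = orig - eps
                down = objective(params)
                arr[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, abs=1e-5), name


def make_toy_fold(n_cells=20, n_pairs=8, seed=0):
    """Linearly separable toy: positive pairs share identical columns."""
    rng = np.random.default_rng(seed)
    genes, counts = [], []
    samples = []
    for i in range(n_pairs):
        base = rng.poisson(20, size=n_cells).astype(float) + 1
        genes += [f"a{i}", f"b{i}", f"n{i}"]
        counts += [base, base, rng.permutation(base)]
        samples.append(PairSample(f"a{i}", f"b{i}", 1))
        samples.append(PairSample(f"a{i}", f"n{i}", 0))
    expr = normalize_counts(np.array(counts).T, gene_ids=genes,
                            cell_ids=[f"c{i}" for i in range(n_cells)])
    train_s = samples[: 2 * (n_pairs - 2)]
    val_s = samples[2 * (n_pairs - 2) :]
    fold = FoldPlan(
        fold_id=0,
        train_ligands={s.gene_a for s in train_s},
        test_ligands=set(),
        train_receptors={s.gene_b for s in train_s},
        test_receptors=set(),
        train_samples=train_s,
        test_samples=[],
        validation_samples=val_s,
    )
    return fold, expr


class TestTrain:
    def test_default_patience_is_half_the_epochs(self):
        assert TrainConfig(epochs=100).effective_patience() == 50
        assert TrainConfig(epochs=7).effective_patience() == 3

    def test_deterministic_given_seed(self):
        fold, expr = make_toy_fold()
        g = diagonal_graph(20, expr.cell_ids)
        cfg = TrainConfig(epochs=6, seed=13, learning_rate=1e-3)
        p1, _ = train(fold, g, expr, cfg)
        p2, _ = train(fold, g, expr, cfg)
        for k, v in p1.arrays().items():
            np.testing.assert_array_equal(v, p2.arrays()[k])

    def test_fits_separable_toy(self):
        fold, expr = make_toy_fold()
        g = diagonal_graph(20, expr.cell_ids)
        cfg = TrainConfig(epochs=60, seed=1, learning_rate=2e-3)
        params, log = train(fold, g, expr, cfg)
        probs = predict(params, g, fold.train_samples, expr)
        y = np.array([s.label for s in fold.train_samples])
        acc = ((probs > 0.5) == (y > 0.5)).mean()
        assert acc == 1.0

    def test_stops_after_patience_stagnant_epochs(self):
        fold, expr = make_toy_fold()
        # freeze learning so validation accuracy never improves
        g = diagonal_graph(20, expr.cell_ids)
        cfg = TrainConfig(epochs=20, seed=2, learning_rate=0.0)
        _, log = train(fold, g, expr, cfg)
        epochs_run = len(log) - 1  # last entry is the summary
        assert epochs_run == 1 + cfg.effective_patience()


class TestPredict:
    def test_batch_matches_single_forward(self):
        fold, expr = make_toy_fold()
        g = diagonal_graph(20, expr.cell_ids)
        params = init_params(20, seed=5)
        probs = predict(params, g, fold.train_samples[:5], expr)
        for s, p in zip(fold.train_samples[:5], probs):
            from spatialgcn.expression import pair_features

            X = pair_features(expr, s.gene_a, s.gene_b, list(g.cell_ids))
            assert p == pytest.approx(forward(g, X, params), abs=1e-9)

    def test_duplicates_get_identical_probabilities(self):
        fold, expr = make_toy_fold()
        g = diagonal_graph(20, expr.cell_ids)
        params = init_params(20, seed=6)
        s = fold.train_samples[0]
        probs = predict(params, g, [s, s], expr)
        assert probs[0] == probs[1]
        assert len(probs) == 2

    def test_unknown_gene_rejected(self):
        fold, expr = make_toy_fold()
        g = diagonal_graph(20, expr.cell_ids)
        params = init_params(20, seed=7)
        with pytest.raises(KeyError):
            predict(params, g, [PairSample("nope", "a0", 1)], expr)


def test_checkpoint_round_trip(tmp_path):
    params = init_params(4, seed=8, channels=3, dense_units=4)
    meta = {"graph_variant": "L_prime", "seed": 8}
    save_checkpoint(params, tmp_path / "model.npz", meta)
    back, meta_back = load_checkpoint(tmp_path / "model.npz")
    for k, v in params.arrays().items():
        np.testing.assert_array_equal(v, back.arrays()[k])
    assert meta_back == meta
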