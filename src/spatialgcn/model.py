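"""The graph-convolutional gene-pair classifier.

Each training sample is one ordered gene pair, represented as an n x 2
matrix X of per-cell normalized expression (column 0 = candidate ligand,
column 1 = candidate receptor).  A fixed n x n graph operator L — shared by
every sample — mixes information across neighboring cells:

    Z = elu(L X W + b)          (graph convolution, 32 channels)

Two such convolutions are stacked (so second-order neighborhoods are
reachable), the n x 32 embedding is flattened through a ReLU, passed
through a 512-unit ReLU dense layer, and a single sigmoid unit outputs the
interaction probability.  Training minimizes the summed binary
cross-entropy with Adam, and early-stops on validation accuracy with a
patience of half the epoch budget.

The whole network, its gradients, and the optimizer are implemented
directly in NumPy; the graph operator is applied as a sparse or dense
matrix product shared across the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .expression import ExpressionMatrix, PairFeatures, pair_features
from .graph import GraphMatrix
from .labels import FoldPlan, PairSample

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "TrainConfig",
    "elu",
    "relu",
    "sigmoid",
    "graph_conv",
    "forward",
    "loss",
    "init_params",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """x for x > 0, alpha*(exp(x) - 1) otherwise."""
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # increasing convention 1/(1+e^{-x})
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ModelParams:
    """All trainable arrays of the five-layer network."""

    W1: np.ndarray  # 2 x 32
    b1: np.ndarray  # 32
    W2: np.ndarray  # 32 x 32
    b2: np.ndarray  # 32
    W_dense: np.ndarray  # (32 n) x 512
    b_dense: np.ndarray  # 512
    w_out: np.ndarray  # 512
    b_out: float
    alpha: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.W_dense.shape[0] // self.W2.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.W1,
            "b1": self.b1,
            "W2": self.W2,
            "b2": self.b2,
            "W_dense": self.W_dense,
            "b_dense": self.b_dense,
            "w_out": self.w_out,
            "b_out": np.asarray(self.b_out, dtype=float),
        }

    def astype(self, dtype) -> "ModelParams":
        return ModelParams(
            W1=self.W1.astype(dtype),
            b1=self.b1.astype(dtype),
            W2=self.W2.astype(dtype),
            b2=self.b2.astype(dtype),
            W_dense=self.W_dense.astype(dtype),
            b_dense=self.b_dense.astype(dtype),
            w_out=self.w_out.astype(dtype),
            b_out=float(self.b_out),
            alpha=self.alpha,
        )

    def copy(self) -> "ModelParams":
        return self.astype(self.W1.dtype)


@dataclass
class TrainConfig:
    """Optimization settings.

    ``patience`` defaults to half the epoch budget; validation accuracy
    must improve within that many epochs or training stops and the
    best-validation parameters are returned.
    """

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 5e-3
    patience: int | None = None
    seed: int = 0
    graph_variant: str = "L_prime"
    dense_units: int = 512
    channels: int = 32

    def effective_patience(self) -> int:
        return self.patience if self.patience is not None else self.epochs // 2


def _as_operator(L) -> np.ndarray | sp.spmatrix:
    if isinstance(L, GraphMatrix):
        return L.M
    return L


def _apply_graph(L, T: np.ndarray) -> np.ndarray:
    """Multiply the n x n operator into stacked features (..., n, c)."""
    if sp.issparse(L):
        if T.ndim == 2:
            return np.asarray(L @ T)
        B, n, c = T.shape
        flat = np.ascontiguousarray(T.transpose(1, 0, 2)).reshape(n, B * c)
        out = np.asarray(L @ flat)
        return out.reshape(n, B, c).transpose(1, 0, 2)
    L = np.asarray(L)
    return np.matmul(L, T)


def graph_conv(L, X: np.ndarray, W: np.ndarray, b: np.ndarray,
               alpha: float = 1.0) -> np.ndarray:
    """One graph convolution: elu(L X W + b)."""
    L = _as_operator(L)
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (cells x channels)")
    n = X.shape[0]
    if L.shape != (n, n):
        raise ValueError(f"graph operator {L.shape} does not match {n} cells")
    if W.shape[0] != X.shape[1]:
        raise ValueError(f"weight rows {W.shape[0]} != input channels {X.shape[1]}")
    if b.shape != (W.shape[1],):
        raise ValueError("bias length does not match output channels")
    return elu(_apply_graph(L, X) @ W + b, alpha=alpha)


def _batch_forward(L, Xb: np.ndarray, params: ModelParams, cache: bool = False):
    """Forward pass over a batch Xb of shape (B, n, 2)."""
    a = params.alpha
    LX = _apply_graph(L, Xb)
    P1 = LX @ params.W1 + params.b1
    Z1 = elu(P1, a)
    LZ1 = _apply_graph(L, Z1)
    P2 = LZ1 @ params.W2 + params.b2
    Z2 = elu(P2, a)
    B = Xb.shape[0]
    F0 = Z2.reshape(B, -1)
    F = relu(F0)
    H0 = F @ params.W_dense + params.b_dense
    H = relu(H0)
    z = H @ params.w_out + params.b_out
    p = sigmoid(z)
    if not cache:
        return p
    return p, {
        "LX": LX, "P1": P1, "Z1": Z1, "LZ1": LZ1, "P2": P2, "Z2": Z2,
        "F0": F0, "F": F, "H0": H0, "H": H, "z": z,
    }


def forward(L, X, params: ModelParams) -> float:
    """Predicted interaction probability for a single gene pair."""
    if isinstance(X, PairFeatures):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("pair input must be n x 2")
    if X.shape[0] != params.n_cells:
        raise ValueError(
            f"input has {X.shape[0]} cells but parameters expect {params.n_cells}"
        )
    Lop = _as_operator(L)
    if Lop.shape != (X.shape[0], X.shape[0]):
        raise ValueError("graph operator does not match the cell count")
    p = _batch_forward(Lop, X[None], params.astype(float))
    return float(p[0])


def loss(labels: Sequence[int], probs: Sequence[float]) -> float:
    """Summed binary cross-entropy over the sample list."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("probabilities outside (0,1) clipped at %g", _EPS)
        p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def init_params(
    n_cells: int,
    seed: int = 0,
    channels: int = 32,
    dense_units: int = 512,
    dtype=np.float64,
) -> ModelParams:
    """Glorot-uniform initialization; biases start at zero."""
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)

    flat = channels * n_cells
    return ModelParams(
        W1=glorot(2, channels),
        b1=np.zeros(channels, dtype=dtype),
        W2=glorot(channels, channels),
        b2=np.zeros(channels, dtype=dtype),
        W_dense=glorot(flat, dense_units),
        b_dense=np.zeros(dense_units, dtype=dtype),
        w_out=glorot(dense_units, 1)[:, 0],
        b_out=0.0,
        alpha=1.0,
    )


def _backward(L, Xb, y, params: ModelParams, cache) -> tuple[dict, float]:
    """Gradients of the mean cross-entropy over the batch."""
    a = params.alpha
    B = Xb.shape[0]
    p = np.clip(cache["p"], _EPS, 1.0 - _EPS)
    mean_loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    dz = (p - y) / B
    g: dict[str, np.ndarray] = {}
    g["w_out"] = cache["H"].T @ dz
    g["b_out"] = dz.sum()
    dH = np.outer(dz, params.w_out)
    dH0 = dH * (cache["H0"] > 0)
    g["W_dense"] = cache["F"].T @ dH0
    g["b_dense"] = dH0.sum(axis=0)
    dF = dH0 @ params.W_dense.T
    dF0 = dF * (cache["F0"] > 0)
    dZ2 = dF0.reshape(cache["Z2"].shape)
    dP2 = dZ2 * np.where(cache["P2"] > 0, 1.0, cache["Z2"] + a)
    g["W2"] = np.einsum("bnc,bnf->cf", cache["LZ1"], dP2)
    g["b2"] = dP2.sum(axis=(0, 1))
    dLZ1 = dP2 @ params.W2.T
    dZ1 = _apply_graph(L.T if sp.issparse(L) else np.asarray(L).T, dLZ1)
    dP1 = dZ1 * np.where(cache["P1"] > 0, 1.0, cache["Z1"] + a)
    g["W1"] = np.einsum("bnc,bnf->cf", cache["LX"], dP1)
    g["b1"] = dP1.sum(axis=(0, 1))
    return g, mean_loss


class _Adam:
    def __init__(self, params: ModelParams, lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays().items()}

    def step(self, params: ModelParams, grads: dict) -> None:
        self.t += 1
        arrays = params.arrays()
        for k, grad in grads.items():
            grad = np.asarray(grad, dtype=arrays[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grad * grad
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k == "b_out":
                params.b_out = float(params.b_out - update)
            else:
                arrays[k] -= update


def _stack_pairs(
    samples: Sequence[PairSample],
    expr: ExpressionMatrix,
    cell_order: Sequence[str] | None,
    dtype,
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack(
        [pair_features(expr, s.gene_a, s.gene_b, cell_order).X for s in samples]
    ).astype(dtype)
    y = np.array([s.label for s in samples], dtype=dtype)
    return X, y


def train(
    fold: FoldPlan,
    graph: GraphMatrix,
    expr: ExpressionMatrix,
    cfg: TrainConfig,
) -> tuple[ModelParams, list[dict]]:
    """Fit the classifier on one fold's training pairs.

    Mini-batch Adam on the cross-entropy objective; after every epoch the
    validation accuracy (0.5 threshold) is measured and the parameters with
    the best validation accuracy so far are retained.  Training stops when
    the validation accuracy has not improved for ``patience`` epochs.
    Fully deterministic given ``cfg.seed``.
    """
    if not fold.train_samples:
        raise ValueError("fold has no training samples")
    if not fold.validation_samples:
        raise ValueError("fold has no validation samples")
    dtype = np.float32
    L = graph.M.astype(dtype) if sp.issparse(graph.M) else np.asarray(graph.M, dtype=dtype)
    order = list(graph.cell_ids)
    Xtr, ytr = _stack_pairs(fold.train_samples, expr, order, dtype)
    Xval, yval = _stack_pairs(fold.validation_samples, expr, order, dtype)
    n = Xtr.shape[1]
    rng = np.random.default_rng(cfg.seed)
    params = init_params(
        n, seed=int(rng.integers(2**31)), channels=cfg.channels,
        dense_units=cfg.dense_units, dtype=dtype,
    )
    opt = _Adam(params, cfg.learning_rate)
    patience = cfg.effective_patience()
    best = params.copy()
    best_acc = -1.0
    best_loss = np.inf
    best_epoch = -1
    stagnant = 0
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        idx = rng.permutation(len(ytr))
        epoch_loss = 0.0
        for start in range(0, len(idx), cfg.batch_size):
            batch = idx[start : start + cfg.batch_size]
            p, cache = _batch_forward(L, Xtr[batch], params, cache=True)
            cache["p"] = p
            grads, mean_loss = _backward(L, Xtr[batch], ytr[batch], params, cache)
            if not np.isfinite(mean_loss):
                raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
            opt.step(params, grads)
            epoch_loss += mean_loss * len(batch)
        pval = _batch_forward(L, Xval, params)
        val_acc = float(((pval > 0.5) == (yval > 0.5)).mean())
        pv = np.clip(pval.astype(np.float64), _EPS, 1 - _EPS)
        val_loss = float(-(yval * np.log(pv) + (1 - yval) * np.log(1 - pv)).mean())
        log.append(
            {"epoch": epoch, "train_loss": epoch_loss,
             "val_accuracy": val_acc, "val_loss": val_loss}
        )
        # accuracy drives early stopping; loss breaks accuracy ties so the
        # retained parameters are not fixed by a lucky early epoch
        if val_acc > best_acc:
            best_acc = val_acc
            best_loss = val_loss
            best = params.copy()
            best_epoch = epoch
            stagnant = 0
        else:
            if val_acc == best_acc and val_loss < best_loss:
                best_loss = val_loss
                best = params.copy()
                best_epoch = epoch
            stagnant += 1
            if stagnant >= patience:
                break
    log.append({"best_epoch": best_epoch, "best_val_accuracy": best_acc})
    return best, log


def predict(
    params: ModelParams,
    graph: GraphMatrix,
    samples: Sequence[PairSample],
    expr: ExpressionMatrix,
    batch_size: int = 64,
) -> np.ndarray:
    """Interaction probabilities for a sample list, order-preserving."""
    if not samples:
        return np.zeros(0)
    p64 = params.astype(np.float64)
    L = graph.M.astype(np.float64) if sp.issparse(graph.M) else np.asarray(
        graph.M, dtype=np.float64
    )
    order = list(graph.cell_ids)
    out = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        X, _ = _stack_pairs(chunk, expr, order, np.float64)
        out.append(_batch_forward(L, X, p64))
    return np.concatenate(out)


def save_checkpoint(
    params: ModelParams, path: str | Path, meta: dict | None = None
) -> None:
    """Portable archive of named arrays plus a JSON sidecar."""
    path = Path(path)
    np.savez(path, **params.arrays(), alpha=params.alpha)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta or {}, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        params = ModelParams(
            W1=data["W1"], b1=data["b1"], W2=data["W2"], b2=data["b2"],
            W_dense=data["W_dense"], b_dense=data["b_dense"],
            w_out=data["w_out"], b_out=float(data["b_out"]),
            alpha=float(data["alpha"]),
        )
    sidecar = Path(str(path).removesuffix(".npz") + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return params, meta
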