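"""Two-layer graph-convolutional classifier and a dense baseline.

Forward pass: H1 = ReLU(A X W0), H2 = ReLU(A H1 W1), P = softmax(H2 W2),
with inverted dropout on H1 and H2 during training. Training is
full-batch Adam on masked categorical cross-entropy with early stopping
on validation accuracy. Gradients are analytic (hand backprop) so they
can be checked against finite differences.

The dense baseline is a 512 -> 256 -> C multilayer perceptron over raw
embeddings trained with the same optimizer and stopping contract, used
by the ablation harness.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from mrigcn.graph import GraphDataset

logger = logging.getLogger(__name__)

_EPS = 1e-12


class MaskError(ValueError):
    pass


class DivergenceError(RuntimeError):
    def __init__(self, msg: str, history: "TrainHistory | None" = None):
        super().__init__(msg)
        self.history = history


@dataclass
class GcnParams:
    W0: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    dropout_p: float = 0.3
    init_seed: int = 42

    def __post_init__(self) -> None:
        d, h = self.W0.shape
        if self.W1.shape != (h, h) or self.W2.shape[0] != h:
            raise ValueError("inconsistent weight shapes")
        if not 0.0 <= self.dropout_p <= 0.5:
            raise ValueError("dropout_p must lie in [0, 0.5]")

    @property
    def hidden_dim(self) -> int:
        return self.W0.shape[1]

    @property
    def n_classes(self) -> int:
        return self.W2.shape[1]

    def copy(self) -> "GcnParams":
        return GcnParams(
            self.W0.copy(), self.W1.copy(), self.W2.copy(), self.dropout_p, self.init_seed
        )


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 20
    patience: int = 3
    steps_per_epoch: int = 50  # full-batch gradient steps per evaluation cycle
    batch_size: int = 16  # used by the dense baseline only
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_acc: float = -np.inf

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as f:
            for e, (l, a) in enumerate(zip(self.train_loss, self.val_acc), start=1):
                f.write(json.dumps({"epoch": e, "loss": l, "val_acc": a}) + "\n")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(d: int, h: int, C: int, seed: int = 42, dropout_p: float = 0.3) -> GcnParams:
    """Glorot-uniform initialization, deterministic by seed."""
    if min(d, h, C) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    return GcnParams(
        W0=_glorot(rng, d, h),
        W1=_glorot(rng, h, h),
        W2=_glorot(rng, h, C),
        dropout_p=dropout_p,
        init_seed=seed,
    )


def gcn_layer(
    A_norm: sp.spmatrix | np.ndarray,
    H: np.ndarray,
    W: np.ndarray,
    activate: bool = True,
) -> np.ndarray:
    """One propagation step: A H W, optionally through ReLU."""
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: H {H.shape} x W {W.shape}")
    out = A_norm @ (H @ W)
    return np.maximum(out, 0.0) if activate else out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _dropout_mask(rng: np.random.Generator, shape, p: float) -> np.ndarray:
    # inverted dropout: scale kept units by 1/(1-p)
    return (rng.random(shape) >= p) / (1.0 - p)


def _forward_pass(
    graph: GraphDataset,
    params: GcnParams,
    training: bool,
    rng: np.random.Generator | None,
) -> dict:
    A, X = graph.A_norm, graph.X
    Z1 = A @ (X @ params.W0)
    H1 = np.maximum(Z1, 0.0)
    if training and params.dropout_p > 0.0:
        if rng is None:
            raise ValueError("training forward pass needs an rng for dropout")
        M1 = _dropout_mask(rng, H1.shape, params.dropout_p)
    else:
        M1 = None
    H1d = H1 if M1 is None else H1 * M1
    Z2 = A @ (H1d @ params.W1)
    H2 = np.maximum(Z2, 0.0)
    if training and params.dropout_p > 0.0:
        M2 = _dropout_mask(rng, H2.shape, params.dropout_p)
    else:
        M2 = None
    H2d = H2 if M2 is None else H2 * M2
    logits = H2d @ params.W2
    P = _softmax(logits)
    return dict(Z1=Z1, H1d=H1d, M1=M1, Z2=Z2, H2d=H2d, M2=M2, P=P)


def forward(
    graph: GraphDataset,
    params: GcnParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) for every node."""
    if graph.A_norm is None:
        raise ValueError("graph is not finalized")
    return _forward_pass(graph, params, training, rng)["P"]


def cross_entropy(probs: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean over masked nodes of -log(probability of the true class)."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise MaskError("empty mask")
    p_true = probs[mask, labels[mask]]
    if np.any(p_true < _EPS):
        warnings.warn("clamping zero probability at true class", RuntimeWarning)
        p_true = np.maximum(p_true, _EPS)
    return float(-np.log(p_true).mean())


def loss_and_grads(
    graph: GraphDataset,
    params: GcnParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Masked cross-entropy and analytic gradients for W0, W1, W2.

    Uses symmetry of the normalized adjacency (A^T = A) when propagating
    gradients back through the two aggregation steps.
    """
    A = graph.A_norm
    cache = _forward_pass(graph, params, training, rng)
    mask = graph.train_mask
    labels = graph.labels
    loss = cross_entropy(cache["P"], labels, mask)

    n_masked = int(mask.sum())
    Y = np.zeros_like(cache["P"])
    midx = np.flatnonzero(mask)
    Y[midx, labels[midx]] = 1.0
    dLogits = np.where(mask[:, None], cache["P"] - Y, 0.0) / n_masked

    gW2 = cache["H2d"].T @ dLogits
    dH2d = dLogits @ params.W2.T
    dH2 = dH2d if cache["M2"] is None else dH2d * cache["M2"]
    dZ2 = dH2 * (cache["Z2"] > 0)
    AdZ2 = A @ dZ2  # A symmetric
    gW1 = cache["H1d"].T @ AdZ2
    dH1d = AdZ2 @ params.W1.T
    dH1 = dH1d if cache["M1"] is None else dH1d * cache["M1"]
    dZ1 = dH1 * (cache["Z1"] > 0)
    AdZ1 = A @ dZ1
    gW0 = graph.X.T @ AdZ1
    return loss, {"W0": gW0, "W1": gW1, "W2": gW2}


class _Adam:
    def __init__(self, shapes: dict[str, tuple], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            weights[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def _accuracy(probs: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    pred = probs.argmax(axis=1)
    return float((pred[mask] == labels[mask]).mean())


def train(
    graph: GraphDataset,
    params: GcnParams,
    cfg: TrainConfig,
) -> tuple[GcnParams, TrainHistory]:
    """Full-batch Adam training with early stopping on validation accuracy.

    Stops when validation accuracy has not strictly improved for
    ``patience`` consecutive epochs, or at ``max_epochs``. Returns the
    parameter snapshot with the best validation accuracy.
    """
    if not graph.train_mask.any() or not graph.val_mask.any():
        raise MaskError("train and val masks must be non-empty")
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)
    weights = {"W0": params.W0, "W1": params.W1, "W2": params.W2}
    opt = _Adam({k: w.shape for k, w in weights.items()}, cfg)
    hist = TrainHistory()
    best = params.copy()
    stagnant = 0
    for epoch in range(1, cfg.max_epochs + 1):
        loss = np.nan
        for _ in range(cfg.steps_per_epoch):
            loss, grads = loss_and_grads(graph, params, training=True, rng=rng)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", hist)
            opt.step(weights, grads)
        probs = forward(graph, params, training=False)
        val_acc = _accuracy(probs, graph.labels, graph.val_mask)
        hist.train_loss.append(loss)
        hist.val_acc.append(val_acc)
        hist.stopped_epoch = epoch
        if val_acc > hist.best_val_acc:
            hist.best_val_acc = val_acc
            hist.best_epoch = epoch
            best = params.copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.patience:
                logger.info("early stop at epoch %d (patience %d)", epoch, cfg.patience)
                break
    return best, hist


def predict(graph: GraphDataset, params: GcnParams, mask: np.ndarray | None = None):
    """Argmax class and max probability per node (default: test nodes).

    Ties break toward the lower class index; test labels are never read.
    """
    probs = forward(graph, params, training=False)
    if mask is None:
        mask = graph.test_mask
    sel = probs[mask]
    return sel.argmax(axis=1), sel.max(axis=1)


# ---------------------------------------------------------------------------
# dense baseline (no graph): embeddings -> 512 -> 256 -> C


@dataclass
class DenseBaseline:
    weights: dict[str, np.ndarray]
    hidden_dims: tuple[int, int] = (512, 256)

    def forward(self, X: np.ndarray) -> np.ndarray:
        w = self.weights
        h1 = np.maximum(X @ w["W0"] + w["b0"], 0.0)
        h2 = np.maximum(h1 @ w["W1"] + w["b1"], 0.0)
        return _softmax(h2 @ w["W2"] + w["b2"])


def dense_baseline_train(
    X: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
    cfg: TrainConfig,
    hidden_dims: tuple[int, int] = (512, 256),
    n_classes: int = 4,
) -> tuple[DenseBaseline, TrainHistory]:
    """Train the MLP baseline with minibatch Adam and the same stopping rule."""
    if not np.any(train_mask) or not np.any(val_mask):
        raise MaskError("train and val masks must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    d = X.shape[1]
    h1, h2 = hidden_dims
    weights = {
        "W0": _glorot(rng, d, h1),
        "b0": np.zeros(h1),
        "W1": _glorot(rng, h1, h2),
        "b1": np.zeros(h2),
        "W2": _glorot(rng, h2, n_classes),
        "b2": np.zeros(n_classes),
    }
    model = DenseBaseline(weights=weights, hidden_dims=hidden_dims)
    opt = _Adam({k: w.shape for k, w in weights.items()}, cfg)
    train_idx = np.flatnonzero(train_mask)
    hist = TrainHistory()
    best_w = {k: w.copy() for k, w in weights.items()}
    stagnant = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        for s in range(0, len(perm), cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            xb, yb = X[idx], labels[idx]
            z1 = xb @ weights["W0"] + weights["b0"]
            a1 = np.maximum(z1, 0.0)
            z2 = a1 @ weights["W1"] + weights["b1"]
            a2 = np.maximum(z2, 0.0)
            probs = _softmax(a2 @ weights["W2"] + weights["b2"])
            p_true = np.maximum(probs[np.arange(len(idx)), yb], _EPS)
            epoch_loss += float(-np.log(p_true).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            dlogits /= len(idx)
            grads = {
                "W2": a2.T @ dlogits,
                "b2": dlogits.sum(0),
            }
            da2 = dlogits @ weights["W2"].T
            dz2 = da2 * (z2 > 0)
            grads["W1"] = a1.T @ dz2
            grads["b1"] = dz2.sum(0)
            da1 = dz2 @ weights["W1"].T
            dz1 = da1 * (z1 > 0)
            grads["W0"] = xb.T @ dz1
            grads["b0"] = dz1.sum(0)
            opt.step(weights, grads)
        epoch_loss /= len(perm)
        if not np.isfinite(epoch_loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}", hist)
        probs = model.forward(X)
        val_acc = _accuracy(probs, labels, val_mask)
        hist.train_loss.append(epoch_loss)
        hist.val_acc.append(val_acc)
        hist.stopped_epoch = epoch
        if val_acc > hist.best_val_acc:
            hist.best_val_acc = val_acc
            hist.best_epoch = epoch
            best_w = {k: w.copy() for k, w in weights.items()}
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.patience:
                break
    return DenseBaseline(weights=best_w, hidden_dims=hidden_dims), hist


def save_checkpoint(params: GcnParams, path: str | Path, meta: dict | None = None) -> None:
    """Single-file checkpoint with weights, dims, dropout and metadata."""
    np.savez(
        path,
        W0=params.W0,
        W1=params.W1,
        W2=params.W2,
        dropout_p=params.dropout_p,
        init_seed=params.init_seed,
        meta=json.dumps(meta or {}),
    )


def load_checkpoint(path: str | Path) -> tuple[GcnParams, dict]:
    with np.load(path, allow_pickle=False) as z:
        params = GcnParams(
            W0=z["W0"],
            W1=z["W1"],
            W2=z["W2"],
            dropout_p=float(z["dropout_p"]),
            init_seed=int(z["init_seed"]),
        )
        meta = json.loads(str(z["meta"]))
    return params, meta
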