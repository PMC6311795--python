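"""Deep belief networks with optional glia-chain pretraining (DBN-GC).

A DBN-GC is a stack of RBMs trained greedily — each layer's CD training
(optionally glia-coupled) sees the previous layer's hidden activation
probabilities — followed by supervised fine-tuning of the whole stack
through a 2-neuron softmax head with backpropagation.  Glia chains act
only during pretraining; every forward pass after training is the pure
deterministic map sigma(W'x + c) layer by layer.

One model is trained per emotion dimension (arousal or valence), so the
label argument everywhere is a single binary vector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .glia import GliaConfig, train_rbm_gc
from .rbm import RBM, TrainConfig, hidden_preactivation, init_rbm, sigmoid

__all__ = ["DBNGC", "pretrain", "finetune", "abstraction", "predict_proba",
           "loss_and_grads"]


def _layer_seed(seed: int, layer: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(10 + layer,))
               .generate_state(1)[0] % (2**31))


@dataclass
class DBNGC:
    """RBM stack plus an optional 2-class softmax head.

    ``layer_sizes`` is (v1, h1, ..., hL); consecutive sizes chain so the
    hidden width of layer k is the visible width of layer k+1.
    """

    layers: list[RBM]
    layer_sizes: tuple[int, ...]
    head_W: np.ndarray | None = None
    head_b: np.ndarray | None = None

    def __post_init__(self):
        sizes = tuple(self.layer_sizes)
        if len(self.layers) != len(sizes) - 1:
            raise ValueError("layer count does not match layer_sizes")
        for k, rbm in enumerate(self.layers):
            if (rbm.n_visible, rbm.n_hidden) != (sizes[k], sizes[k + 1]):
                raise ValueError(f"layer {k} shape breaks the size chain")
        if self.head_W is not None and self.head_W.shape != (sizes[-1], 2):
            raise ValueError("head input width must equal last hidden size")

    @classmethod
    def build(cls, layer_sizes, seed: int = 0,
              visible_type: str = "gaussian") -> "DBNGC":
        """Fresh stack with seeded Gaussian(0, 0.01) weights.

        The first layer uses ``visible_type`` (Gaussian by default, for
        z-scored feature input); upper layers are binary-visible since
        they consume activation probabilities.
        """
        sizes = tuple(int(s) for s in layer_sizes)
        layers = [
            init_rbm(sizes[k], sizes[k + 1], seed=_layer_seed(seed, k),
                     visible_type=visible_type if k == 0 else "binary")
            for k in range(len(sizes) - 1)
        ]
        return cls(layers=layers, layer_sizes=sizes)

    @property
    def n_input(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_output(self) -> int:
        return self.layer_sizes[-1]


def _forward_hidden(dbn: DBNGC, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input included at index 0, batch rows.

    A stack with no layers (layer_sizes of length 1) is a passthrough:
    its "last hidden" output is the input itself.
    """
    a = np.atleast_2d(np.asarray(X, dtype=float))
    if a.shape[1] != dbn.n_input:
        raise ValueError(f"input width {a.shape[1]} != model input {dbn.n_input}")
    acts = [a]
    for rbm in dbn.layers:
        a = sigmoid(hidden_preactivation(rbm, a))
        acts.append(a)
    return acts


def pretrain(dbn: DBNGC, data: np.ndarray, cfg: TrainConfig,
             glia: GliaConfig | None = None) -> DBNGC:
    """Greedy layer-wise CD pretraining, bottom to top.

    Each layer is trained (glia-coupled when ``glia`` is given) on the
    activation probabilities produced by the already-trained layers
    below it; training layer k never touches layers < k.
    """
    rep = np.atleast_2d(np.asarray(data, dtype=float))
    if rep.shape[1] != dbn.n_input:
        raise ValueError("data width does not match the first visible layer")
    for k in range(len(dbn.layers)):
        layer_cfg = replace(
            cfg, seed=_layer_seed(cfg.seed, k),
            visible_type=dbn.layers[k].visible_type)
        dbn.layers[k] = train_rbm_gc(rep, dbn.layer_sizes[k + 1], layer_cfg,
                                     glia=glia)
        rep = sigmoid(hidden_preactivation(dbn.layers[k], rep))
    return dbn


def loss_and_grads(dbn: DBNGC, X: np.ndarray, y: np.ndarray):
    """Mean cross-entropy of the softmax head and its gradients.

    Returns (loss, grads) with grads a dict holding per-layer ``W``/``c``
    lists and ``head_W``/``head_b``.  Visible biases do not enter the
    forward pass and receive no gradient.
    """
    if dbn.head_W is None:
        raise ValueError("model has no supervised head")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).reshape(-1)
    n = X.shape[0]
    acts = _forward_hidden(dbn, X)
    logits = acts[-1] @ dbn.head_W + dbn.head_b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-300, None)).mean())

    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y] = 1.0
    delta = (p - onehot) / n  # d loss / d logits
    g_head_W = acts[-1].T @ delta
    g_head_b = delta.sum(axis=0)

    gW = [None] * len(dbn.layers)
    gc = [None] * len(dbn.layers)
    back = delta @ dbn.head_W.T
    for k in range(len(dbn.layers) - 1, -1, -1):
        a = acts[k + 1]
        dz = back * a * (1.0 - a)
        gW[k] = acts[k].T @ dz
        gc[k] = dz.sum(axis=0)
        if k > 0:
            back = dz @ dbn.layers[k].W.T
    return loss, {"W": gW, "c": gc, "head_W": g_head_W, "head_b": g_head_b}


def finetune(dbn: DBNGC, data: np.ndarray, labels: np.ndarray,
             cfg: TrainConfig, patience: int = 20,
             min_delta: float = 1e-5) -> DBNGC:
    """Supervised fine-tuning of the full stack plus a 2-neuron head.

    Plain SGD with momentum on mean cross-entropy; stops early when the
    epoch training loss has not improved by ``min_delta`` for
    ``patience`` epochs.  Glia terms are absent here by construction.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    y = np.asarray(labels, dtype=int).reshape(-1)
    if X.shape[0] != y.size:
        raise ValueError("data and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(99,)))
    if dbn.head_W is None:
        dbn.head_W = 0.01 * rng.standard_normal((dbn.n_output, 2))
        dbn.head_b = np.zeros(2)

    vel_W = [np.zeros_like(r.W) for r in dbn.layers]
    vel_c = [np.zeros_like(r.c) for r in dbn.layers]
    vel_hW = np.zeros_like(dbn.head_W)
    vel_hb = np.zeros_like(dbn.head_b)
    idx = np.arange(X.shape[0])
    best, since_best = np.inf, 0
    for _ in range(cfg.epochs):
        rng.shuffle(idx)
        epoch_loss = 0.0
        for s in range(0, idx.size, cfg.batch_size):
            b = idx[s:s + cfg.batch_size]
            loss, g = loss_and_grads(dbn, X[b], y[b])
            epoch_loss += loss * b.size
            lr, mom = cfg.learning_rate, cfg.momentum
            for k, rbm in enumerate(dbn.layers):
                vel_W[k] = mom * vel_W[k] - lr * (g["W"][k] + cfg.weight_decay * rbm.W)
                vel_c[k] = mom * vel_c[k] - lr * g["c"][k]
                rbm.W += vel_W[k]
                rbm.c += vel_c[k]
            vel_hW = mom * vel_hW - lr * (g["head_W"] + cfg.weight_decay * dbn.head_W)
            vel_hb = mom * vel_hb - lr * g["head_b"]
            dbn.head_W += vel_hW
            dbn.head_b += vel_hb
        epoch_loss /= idx.size
        if epoch_loss < best - min_delta:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return dbn


def abstraction(dbn: DBNGC, x: np.ndarray) -> np.ndarray:
    """Deterministic last-hidden-layer output; the head is ignored.

    Accepts a single vector or a batch of rows.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = _forward_hidden(dbn, x)[-1]
    return out[0] if single else out


def predict_proba(dbn: DBNGC, X: np.ndarray) -> np.ndarray:
    """Softmax head class probabilities, shape (n, 2)."""
    if dbn.head_W is None:
        raise ValueError("model has no supervised head")
    a = _forward_hidden(dbn, X)[-1]
    logits = a @ dbn.head_W + dbn.head_b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)
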