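"""Restricted Boltzmann machines: CD training, exact small-model
inference, and a discriminative RBM classifier.

The RBM energy is E(v, h) = -v'Wh - b'v - c'h with visible units either
binary or Gaussian with unit variance (the default for z-scored feature
input).  Hidden activation probabilities, not Bernoulli samples, are used
as hidden outputs, which reduces sampling noise; the one Gibbs step of
CD-1 still samples the hidden states.

Models small enough to enumerate (<= 20 units) expose exact
log-likelihood, its analytic gradient and the exact visible distribution,
used as independent oracles by the test suite.

The discriminative RBM augments the visible layer with a one-hot label
group of size 2 and is trained on the exact conditional likelihood
p(y|x), which for two classes is computed in closed form by free-energy
comparison — no sampling is involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "RBM",
    "TrainConfig",
    "DiscriminativeRBM",
    "init_rbm",
    "hidden_preactivation",
    "hidden_probability",
    "sigmoid",
    "cd_update",
    "train_rbm",
    "exact_log_likelihood",
    "exact_visible_distribution",
    "exact_grad_log_likelihood",
    "gibbs_sample",
    "init_discriminative_rbm",
    "train_discriminative_rbm",
    "predict",
    "save_rbm",
    "load_rbm",
]

_ENUM_LIMIT = 20


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class TrainConfig:
    """Hyperparameters shared by CD pretraining and the discriminative RBM.

    Defaults: mean-gradient over mini-batches of 8, momentum 0.5, weight
    decay 1e-4, 100 epochs of CD-1.
    """

    learning_rate: float = 0.05
    batch_size: int = 8
    epochs: int = 100
    cd_k: int = 1
    momentum: float = 0.5
    weight_decay: float = 1e-4
    seed: int = 0
    visible_type: str = "gaussian"  # "gaussian" (unit variance) or "binary"
    sample_hidden: bool = True

    def __post_init__(self):
        if self.visible_type not in ("gaussian", "binary"):
            raise ValueError("visible_type must be 'gaussian' or 'binary'")
        if self.cd_k < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training hyperparameters")


@dataclass
class RBM:
    """Weights W (visible x hidden), visible biases b, hidden biases c."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    visible_type: str = "binary"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.W.shape != (self.b.size, self.c.size):
            raise ValueError("inconsistent parameter shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))
                and np.all(np.isfinite(self.c))):
            raise ValueError("non-finite parameters")

    @property
    def n_visible(self) -> int:
        return self.b.size

    @property
    def n_hidden(self) -> int:
        return self.c.size


def init_rbm(n_visible: int, n_hidden: int, seed: int = 0,
             visible_type: str = "binary", weight_scale: float = 0.01) -> RBM:
    """Gaussian(0, weight_scale) weights, zero biases, seeded."""
    rng = np.random.default_rng(seed)
    W = weight_scale * rng.standard_normal((n_visible, n_hidden))
    return RBM(W=W, b=np.zeros(n_visible), c=np.zeros(n_hidden),
               visible_type=visible_type)


def hidden_preactivation(rbm: RBM, v: np.ndarray) -> np.ndarray:
    """h* = W'v + c for a vector or a batch of row vectors."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != rbm.n_visible:
        raise ValueError(
            f"visible width {v.shape[-1]} != model width {rbm.n_visible}")
    return v @ rbm.W + rbm.c


def hidden_probability(h_star: np.ndarray) -> np.ndarray:
    """Hidden activation probabilities sigma(h*), used directly as outputs."""
    return sigmoid(np.asarray(h_star, dtype=float))


def _reconstruct_visible(rbm: RBM, h: np.ndarray) -> np.ndarray:
    pre = h @ rbm.W.T + rbm.b
    return sigmoid(pre) if rbm.visible_type == "binary" else pre


def cd_update(rbm: RBM, batch: np.ndarray, cfg: TrainConfig,
              rng: np.random.Generator | None = None,
              hidden_fn=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One CD-k mean-gradient step; returns learning-rate-scaled deltas.

    Positive phase uses hidden probabilities of the data; the negative
    phase samples hidden states, reconstructs the visible layer as
    probabilities (means for Gaussian units) and reuses hidden
    probabilities.  ``hidden_fn(h_star)`` overrides the hidden output
    rule (the glia coupling hooks in here); it defaults to sigma.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    act = hidden_fn if hidden_fn is not None else hidden_probability
    n = batch.shape[0]

    h_pos = act(hidden_preactivation(rbm, batch))
    v_neg = batch
    h_prob = h_pos
    for _ in range(cfg.cd_k):
        h_state = (rng.random(h_prob.shape) < h_prob).astype(float) \
            if cfg.sample_hidden else h_prob
        v_neg = _reconstruct_visible(rbm, h_state)
        h_prob = act(hidden_preactivation(rbm, v_neg))
    h_neg = h_prob

    lr = cfg.learning_rate
    dW = lr * ((batch.T @ h_pos - v_neg.T @ h_neg) / n - cfg.weight_decay * rbm.W)
    db = lr * (batch - v_neg).mean(axis=0)
    dc = lr * (h_pos - h_neg).mean(axis=0)
    return dW, db, dc


def train_rbm(data: np.ndarray, n_hidden: int, cfg: TrainConfig,
              chain=None) -> RBM:
    """CD training loop with momentum and seeded shuffling.

    When a :class:`~gliadbn.glia.GliaChain` is supplied, it is advanced
    once per mini-batch on the batch-mean preactivation and its effect
    is added to every hidden output of that batch (pretraining only;
    the returned model is glia-free).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rbm = init_rbm(data.shape[1], n_hidden, seed=cfg.seed,
                   visible_type=cfg.visible_type)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    vW = np.zeros_like(rbm.W)
    vb = np.zeros_like(rbm.b)
    vc = np.zeros_like(rbm.c)
    idx = np.arange(data.shape[0])
    for _ in range(cfg.epochs):
        rng.shuffle(idx)
        for s in range(0, idx.size, cfg.batch_size):
            batch = data[idx[s:s + cfg.batch_size]]
            if chain is not None:
                from .glia import glia_hidden_output, glia_step
                mean_pre = hidden_preactivation(rbm, batch).mean(axis=0)
                glia_step(chain, mean_pre)
                hidden_fn = lambda h_star: glia_hidden_output(h_star, chain)
            else:
                hidden_fn = None
            dW, db, dc = cd_update(rbm, batch, cfg, rng=rng, hidden_fn=hidden_fn)
            vW = cfg.momentum * vW + dW
            vb = cfg.momentum * vb + db
            vc = cfg.momentum * vc + dc
            rbm.W += vW
            rbm.b += vb
            rbm.c += vc
    return rbm


# ---------------------------------------------------------------------------
# Exact oracles for enumerable (binary-binary) models
# ---------------------------------------------------------------------------

def _check_enumerable(rbm: RBM) -> None:
    if rbm.visible_type != "binary":
        raise ValueError("exact enumeration requires binary visible units")
    if rbm.n_visible + rbm.n_hidden > _ENUM_LIMIT:
        raise ValueError(f"model too large to enumerate (> {_ENUM_LIMIT} units)")


def _all_configs(n: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


def _unnormalized_logp(rbm: RBM, V: np.ndarray) -> np.ndarray:
    # log p~(v) = b'v + sum_j softplus(c_j + (v W)_j), hidden summed out
    return V @ rbm.b + _softplus(V @ rbm.W + rbm.c).sum(axis=1)


def exact_log_likelihood(rbm: RBM, v: np.ndarray) -> float:
    """log p(v) by full enumeration (binary models, <= 20 units total)."""
    _check_enumerable(rbm)
    v = np.asarray(v, dtype=float).reshape(-1)
    if v.size != rbm.n_visible:
        raise ValueError("visible width mismatch")
    V = _all_configs(rbm.n_visible)
    logp = _unnormalized_logp(rbm, V)
    log_z = float(np.logaddexp.reduce(logp))
    return float(_unnormalized_logp(rbm, v[None, :])[0] - log_z)


def exact_visible_distribution(rbm: RBM) -> tuple[np.ndarray, np.ndarray]:
    """(configs, probabilities) over all 2^n_visible states."""
    _check_enumerable(rbm)
    V = _all_configs(rbm.n_visible)
    logp = _unnormalized_logp(rbm, V)
    logp -= np.logaddexp.reduce(logp)
    return V, np.exp(logp)


def exact_grad_log_likelihood(rbm: RBM, data: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact ML gradient of the mean log-likelihood of ``data``.

    Positive phase uses p(h|v) on the data; the model expectation is
    computed by enumeration.
    """
    _check_enumerable(rbm)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    h_data = sigmoid(data @ rbm.W + rbm.c)
    V, p = exact_visible_distribution(rbm)
    h_model = sigmoid(V @ rbm.W + rbm.c)
    dW = data.T @ h_data / data.shape[0] - (V * p[:, None]).T @ h_model
    db = data.mean(axis=0) - p @ V
    dc = h_data.mean(axis=0) - p @ h_model
    return dW, db, dc


def gibbs_sample(rbm: RBM, n_sweeps: int, seed: int = 0,
                 burn_in: int = 100) -> np.ndarray:
    """Visible samples from alternating Gibbs sweeps (binary models)."""
    if rbm.visible_type != "binary":
        raise ValueError("Gibbs sampler implemented for binary visible units")
    rng = np.random.default_rng(seed)
    v = (rng.random(rbm.n_visible) < 0.5).astype(float)
    out = np.empty((n_sweeps, rbm.n_visible))
    for t in range(burn_in + n_sweeps):
        h = (rng.random(rbm.n_hidden) < sigmoid(v @ rbm.W + rbm.c)).astype(float)
        v = (rng.random(rbm.n_visible) < sigmoid(h @ rbm.W.T + rbm.b)).astype(float)
        if t >= burn_in:
            out[t - burn_in] = v
    return out


# ---------------------------------------------------------------------------
# Discriminative RBM (2-class)
# ---------------------------------------------------------------------------

@dataclass
class DiscriminativeRBM:
    """RBM whose visible layer carries a one-hot 2-class label group.

    W: feature-to-hidden weights (n_features x n_hidden); U: label-to-
    hidden weights (2 x n_hidden); d: label biases (2,).  The class
    posterior p(y|x) is exact: softmax over y of
    d_y + sum_j softplus(c_j + U_yj + (x W)_j).
    """

    W: np.ndarray
    U: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.U.shape != (2, self.c.size) or self.d.shape != (2,):
            raise ValueError("label group must have exactly 2 classes")
        if self.W.shape[1] != self.c.size:
            raise ValueError("inconsistent hidden width")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.c.size


def init_discriminative_rbm(n_features: int, n_hidden: int, seed: int = 0,
                            weight_scale: float = 0.01) -> DiscriminativeRBM:
    rng = np.random.default_rng(seed)
    return DiscriminativeRBM(
        W=weight_scale * rng.standard_normal((n_features, n_hidden)),
        U=weight_scale * rng.standard_normal((2, n_hidden)),
        c=np.zeros(n_hidden),
        d=np.zeros(2),
    )


def _class_scores(model: DiscriminativeRBM, X: np.ndarray) -> np.ndarray:
    """Negative label-conditional free energies, shape (n, 2)."""
    XW = X @ model.W  # (n, nh)
    scores = np.empty((X.shape[0], 2))
    for y in (0, 1):
        scores[:, y] = model.d[y] + _softplus(XW + model.c + model.U[y]).sum(axis=1)
    return scores


def predict(model: DiscriminativeRBM, features: np.ndarray) -> np.ndarray:
    """Exact p(y|x) per row by free-energy comparison; shape (n, 2)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature width mismatch")
    s = _class_scores(model, X)
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def _drbm_grads(model: DiscriminativeRBM, X: np.ndarray, y: np.ndarray):
    """Gradients of the mean negative log p(y|x)."""
    n = X.shape[0]
    p = predict(model, X)  # (n, 2)
    XW = X @ model.W
    gW = np.zeros_like(model.W)
    gU = np.zeros_like(model.U)
    gc = np.zeros_like(model.c)
    gd = np.zeros_like(model.d)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y] = 1.0
    resid = onehot - p  # (n, 2): positive for the true class
    gd = -resid.mean(axis=0)
    for cls in (0, 1):
        hp = sigmoid(XW + model.c + model.U[cls])  # (n, nh)
        w = resid[:, cls][:, None] * hp
        gW -= X.T @ w / n
        gU[cls] -= w.mean(axis=0)
        gc -= w.mean(axis=0)
    return gW, gU, gc, gd


def train_discriminative_rbm(features: np.ndarray, labels: np.ndarray,
                             cfg: TrainConfig | None = None,
                             n_hidden: int = 20) -> DiscriminativeRBM:
    """Fit by mini-batch gradient descent on the exact NLL of p(y|x)."""
    if cfg is None:
        cfg = TrainConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int).reshape(-1)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    model = init_discriminative_rbm(X.shape[1], n_hidden, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    vel = [np.zeros_like(p) for p in (model.W, model.U, model.c, model.d)]
    idx = np.arange(X.shape[0])
    for _ in range(cfg.epochs):
        rng.shuffle(idx)
        for s in range(0, idx.size, cfg.batch_size):
            b = idx[s:s + cfg.batch_size]
            grads = _drbm_grads(model, X[b], y[b])
            params = (model.W, model.U, model.c, model.d)
            for k, (p, g) in enumerate(zip(params, grads)):
                vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * g
                p += vel[k]
    return model


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_rbm(path, rbm: RBM) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=rbm.W)
        f.create_dataset("b", data=rbm.b)
        f.create_dataset("c", data=rbm.c)
        f.attrs["visible_type"] = rbm.visible_type


def load_rbm(path) -> RBM:
    with h5py.File(path, "r") as f:
        return RBM(W=f["W"][()], b=f["b"][()], c=f["c"][()],
                   visible_type=f.attrs["visible_type"])
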