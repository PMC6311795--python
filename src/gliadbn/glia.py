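"""Glia chain: a linear lattice of auxiliary cells coupled to an RBM's
hidden layer during contrastive-divergence pretraining.

Each hidden unit j owns one glia cell with effect value g_j in [0, 1].
At each discrete step a cell fires (g_j <- 1) when it is outside its
refractory window and either its hidden unit's activation probability
sigma(h*_j) exceeds the threshold theta, or the preceding cell on the
chain fired at the previous step; otherwise its effect decays,
g_j <- beta * g_j.  Firing therefore propagates as a wavefront, one link
per step, from the first cell toward the last.  During pretraining the
hidden output rule becomes

    h_j = sigma(h*_j + alpha * g_j)

with alpha a manually set coupling weight.  The chain acts only during
pretraining; trained models are glia-free at inference.

The threshold is compared against sigma(h*) (not the raw preactivation)
so that theta's natural [0, 1] sweep range is meaningful, and the timing
condition is implemented with refractory semantics: a cell that fired at
step s cannot fire again before step s + T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rbm import RBM, TrainConfig, sigmoid, train_rbm

__all__ = ["GliaConfig", "GliaChain", "glia_step", "glia_hidden_output",
           "train_rbm_gc"]


@dataclass(frozen=True)
class GliaConfig:
    """Chain hyperparameters: coupling weight alpha, decay beta,
    firing threshold theta (all in [0, 1]) and refractory period T >= 1
    (in chain steps, i.e. mini-batch updates)."""

    alpha: float = 0.8
    beta: float = 0.4
    theta: float = 0.75
    T_refractory: int = 5

    def __post_init__(self):
        for name in ("alpha", "beta", "theta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.T_refractory < 1:
            raise ValueError("T_refractory must be >= 1")


@dataclass
class GliaChain:
    """Mutable chain state paired with one RBM hidden layer.

    ``order[k]`` is the hidden-unit index at chain position k (defaults
    to identity); ``last_fire`` tracks each cell's last activation step
    for the refractory rule, ``prev_fired`` the firing flags of the
    previous step (in chain-position space) that drive propagation.
    """

    g: np.ndarray
    last_fire: np.ndarray
    prev_fired: np.ndarray
    order: np.ndarray
    config: GliaConfig
    step: int = 0

    @classmethod
    def create(cls, n_hidden: int, config: GliaConfig | None = None,
               order=None) -> "GliaChain":
        if config is None:
            config = GliaConfig()
        order = np.arange(n_hidden) if order is None else np.asarray(order, int)
        if sorted(order.tolist()) != list(range(n_hidden)):
            raise ValueError("order must be a permutation of hidden indices")
        return cls(
            g=np.zeros(n_hidden),
            last_fire=np.full(n_hidden, np.iinfo(np.int64).min // 2, dtype=np.int64),
            prev_fired=np.zeros(n_hidden, dtype=bool),
            order=order,
            config=config,
        )


def glia_step(chain: GliaChain, h_star: np.ndarray) -> np.ndarray:
    """Advance the chain one step on preactivations ``h_star``.

    Returns the fired flags (hidden-index space).  A cell fires iff it is
    refractory-eligible and (sigma(h*) > theta or its chain predecessor
    fired at the previous step); non-firing cells decay by beta.
    """
    h_star = np.asarray(h_star, dtype=float)
    if h_star.shape != chain.g.shape:
        raise ValueError("h_star length does not match chain length")
    cfg = chain.config
    eligible = (chain.step - chain.last_fire) >= cfg.T_refractory
    over = sigmoid(h_star) > cfg.theta

    # predecessor signal, one link per step along the chain order
    pred = np.zeros(chain.g.size, dtype=bool)
    pred[1:] = chain.prev_fired[:-1]

    pos = chain.order  # hidden index at each chain position
    fired_pos = eligible[pos] & (over[pos] | pred)
    fired = np.zeros(chain.g.size, dtype=bool)
    fired[pos[fired_pos]] = True

    chain.g = np.where(fired, 1.0, cfg.beta * chain.g)
    chain.last_fire[fired] = chain.step
    chain.prev_fired = fired_pos
    chain.step += 1
    return fired


def glia_hidden_output(h_star: np.ndarray, chain: GliaChain) -> np.ndarray:
    """Glia-coupled hidden output h = sigma(h* + alpha * g)."""
    h_star = np.asarray(h_star, dtype=float)
    if h_star.shape[-1] != chain.g.size:
        raise ValueError("h_star width does not match chain length")
    return sigmoid(h_star + chain.config.alpha * chain.g)


def train_rbm_gc(data: np.ndarray, n_hidden: int, cfg: TrainConfig,
                 glia: GliaConfig | None = None, order=None) -> RBM:
    """CD pretraining with the glia coupling active.

    The chain advances once per mini-batch, driven by the batch-mean
    preactivation, and its effect enters the hidden outputs of both CD
    phases.  With ``glia=None`` (or alpha = 0) the parameter trajectory
    is identical to plain :func:`~gliadbn.rbm.train_rbm` under the same
    seed.  The returned RBM carries no glia state: inference uses plain
    sigma(h*).
    """
    chain = None
    if glia is not None:
        chain = GliaChain.create(n_hidden, config=glia, order=order)
    return train_rbm(data, n_hidden, cfg, chain=chain)
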