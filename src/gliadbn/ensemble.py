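"""Five-branch DBN-GC ensemble fused by a discriminative RBM.

The 664-wide feature vector is split into its five physiological subsets
F1..F5; one DBN-GC per subset learns an intermediate abstraction (its
last hidden layer), the five abstractions are concatenated (350 wide
with the default layer sizes) and a discriminative RBM classifies the
fused vector.  Training is stagewise: branches first (greedy pretrain +
supervised fine-tune, each with a temporary 2-neuron head that is
ignored afterwards), then the fusion RBM on the frozen abstractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .dbn import DBNGC, abstraction, finetune, pretrain
from .features import FeatureSchema, FeatureVector
from .glia import GliaConfig
from .rbm import DiscriminativeRBM, TrainConfig
from .rbm import predict as drbm_predict
from .rbm import train_discriminative_rbm

__all__ = ["DEFAULT_BRANCH_SIZES", "EnsembleConfig", "EnsembleModel",
           "split_subsets", "train_ensemble", "predict_ensemble",
           "sweep_glia_params", "default_sweep_grid"]

SUBSET_KEYS = ("F1", "F2", "F3", "F4", "F5")

#: Default hidden layer sizes (h1, h2, h3) per branch; last-hidden sum 350.
DEFAULT_BRANCH_SIZES: dict[str, tuple[int, int, int]] = {
    "F1": (110, 105, 90),
    "F2": (145, 145, 120),
    "F3": (55, 55, 45),
    "F4": (120, 55, 45),
    "F5": (155, 80, 50),
}


@dataclass(frozen=True)
class EnsembleConfig:
    """Full configuration of the five-branch ensemble.

    Layer sizes, glia parameters and all optimizer settings are exposed
    because none of them is forced by the architecture; the defaults are
    the reference configuration (350-wide fusion input, alpha=0.8,
    beta=0.4, theta=0.75, T=5).
    """

    branch_sizes: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_SIZES))
    glia: GliaConfig | None = field(default_factory=GliaConfig)
    pretrain: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.005, epochs=30))
    finetune: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.3, momentum=0.9,
                                            epochs=150))
    fusion: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.1, epochs=150))
    fusion_hidden: int = 50
    seed: int = 0

    def fusion_width(self) -> int:
        return sum(self.branch_sizes[k][-1] for k in SUBSET_KEYS)


@dataclass
class EnsembleModel:
    """Trained branches keyed F1..F5 plus the fusion discriminative RBM."""

    branches: dict[str, DBNGC]
    fusion: DiscriminativeRBM
    schema: FeatureSchema
    config: EnsembleConfig

    def __post_init__(self):
        width = sum(self.branches[k].n_output for k in SUBSET_KEYS)
        if self.fusion.n_features != width:
            raise ValueError("fusion input width != sum of branch outputs")


def split_subsets(x, schema: FeatureSchema | None = None) -> dict[str, np.ndarray]:
    """Split a 664-wide vector (or row batch) into the five subvectors.

    Concatenating the results in F1..F5 order reconstructs the input.
    """
    if isinstance(x, FeatureVector):
        schema = x.schema
        x = x.values
    if schema is None:
        schema = FeatureSchema.default()
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(schema):
        raise ValueError(f"vector width {x.shape[-1]} != schema width {len(schema)}")
    out = {}
    for key in SUBSET_KEYS:
        r = schema.subset_index[key]
        out[key] = x[..., r.start:r.stop]
    return out


def _branch_seed(seed: int, branch: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(branch,))
               .generate_state(1)[0] % (2**31))


def train_ensemble(train_matrix: np.ndarray, labels: np.ndarray,
                   config: EnsembleConfig | None = None,
                   schema: FeatureSchema | None = None,
                   seed: int | None = None) -> EnsembleModel:
    """Stagewise ensemble training on a standardized feature matrix.

    ``labels`` is a single binary vector (one emotion dimension).  The
    five branches are trained first — glia chains active during their
    pretraining only — then the fusion discriminative RBM is fit on the
    concatenated abstractions; fitting the fusion never mutates branch
    weights.  Fully deterministic given the seed.
    """
    if config is None:
        config = EnsembleConfig()
    if schema is None:
        schema = FeatureSchema.default()
    if seed is None:
        seed = config.seed
    X = np.atleast_2d(np.asarray(train_matrix, dtype=float))
    y = np.asarray(labels, dtype=int).reshape(-1)
    subsets = split_subsets(X, schema)

    branches: dict[str, DBNGC] = {}
    for i, key in enumerate(SUBSET_KEYS):
        Xi = subsets[key]
        bseed = _branch_seed(seed, i)
        sizes = (Xi.shape[1], *config.branch_sizes[key])
        dbn = DBNGC.build(sizes, seed=bseed,
                          visible_type=config.pretrain.visible_type)
        pretrain(dbn, Xi, replace(config.pretrain, seed=bseed),
                 glia=config.glia)
        finetune(dbn, Xi, y, replace(config.finetune, seed=bseed))
        branches[key] = dbn

    fused = np.hstack([abstraction(branches[k], subsets[k]) for k in SUBSET_KEYS])
    fusion = train_discriminative_rbm(
        fused, y, replace(config.fusion, seed=_branch_seed(seed, 5)),
        n_hidden=config.fusion_hidden)
    return EnsembleModel(branches=branches, fusion=fusion, schema=schema,
                         config=config)


def predict_ensemble(model: EnsembleModel, test_matrix: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(class probabilities, predicted labels) for 664-wide rows."""
    X = np.atleast_2d(np.asarray(test_matrix, dtype=float))
    subsets = split_subsets(X, model.schema)
    fused = np.hstack([abstraction(model.branches[k], subsets[k])
                       for k in SUBSET_KEYS])
    probs = drbm_predict(model.fusion, fused)
    return probs, probs.argmax(axis=1)


def default_sweep_grid() -> np.ndarray:
    """The 20-point parameter grid 0.05, 0.10, ..., 1.00."""
    return np.round(np.arange(1, 21) * 0.05, 2)


def sweep_glia_params(param: str, grid, features_by_subject, config=None,
                      k: int = 10, seed: int = 0,
                      strict_cv: bool = False) -> pd.DataFrame:
    """Mean recognition accuracy per value of one glia parameter.

    ``param`` is one of alpha / beta / theta; the other glia parameters
    stay at the config defaults.  Each grid value is evaluated with
    subject-wise k-fold cross-validation and the table reports the mean
    accuracy per emotion dimension (rows = grid size x 2 dimensions).
    """
    from .evaluation import run_cv  # deferred: evaluation imports this module

    if param not in ("alpha", "beta", "theta"):
        raise ValueError("param must be one of alpha, beta, theta")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid values must lie in [0, 1]")
    if config is None:
        config = EnsembleConfig()
    base_glia = config.glia if config.glia is not None else GliaConfig()

    rows = []
    for value in grid:
        cfg = replace(config, glia=replace(base_glia, **{param: float(value)}))
        result = run_cv(features_by_subject, cfg, k=k, seed=seed,
                        strict_cv=strict_cv)
        agg = result.aggregate()
        for dim in agg.index:
            rows.append({"param": param, "value": float(value),
                         "dimension": dim,
                         "mean_accuracy": float(agg.loc[dim, "accuracy_mean"])})
    return pd.DataFrame(rows)
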