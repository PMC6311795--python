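"""Participant-specific k-fold cross-validation and metrics.

Each subject's instances are split into k folds (10 by default: nine
folds of training, one of test, rotated until every instance has been
tested).  Feature standardization follows the protocol the pipeline
reproduces: each subject's full instance matrix is z-scored before
splitting, which leaks test statistics into training; the ``strict_cv``
switch instead standardizes with training-fold statistics only and
applies them to the held-out fold.

Metrics are accuracy and the positive-class (high arousal / high
valence) F1 score; macro-F1 is available via a flag.  One model is
trained per emotion dimension per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import sklearn.metrics as skm
from sklearn.model_selection import KFold, StratifiedKFold

from .dbn import DBNGC, finetune, predict_proba, pretrain
from .ensemble import EnsembleConfig, predict_ensemble, train_ensemble
from .features import apply_standardization, extract_subject, standardize_subject
from .glia import GliaConfig
from .rbm import TrainConfig

__all__ = ["DIMENSIONS", "SUBSET_SLICES", "TABLE_DBN_SIZES", "DBNModelConfig",
           "CVResult", "make_folds", "accuracy", "f1_score", "run_cv",
           "evaluate_dataset", "compare_glia_variants"]

DIMENSIONS = ("arousal", "valence")

#: Column ranges of the composite feature subsets used for single-DBN runs:
#: F6 = time stats, F7 = band PSDs + power differences, F8 = both HHS blocks,
#: F0 = everything.
SUBSET_SLICES: dict[str, tuple[int, int]] = {
    "F6": (0, 128), "F7": (128, 344), "F8": (344, 664), "F0": (0, 664),
}

#: Reference hidden sizes (h1, h2, h3) for the single-DBN comparison runs.
TABLE_DBN_SIZES: dict[str, tuple[int, int, int]] = {
    "F6": (100, 80, 45), "F7": (200, 135, 90), "F8": (300, 280, 125),
}


@dataclass(frozen=True)
class DBNModelConfig:
    """A single DBN(-GC) on one composite feature subset."""

    subset: str = "F7"
    hidden_sizes: tuple[int, ...] | None = None  # default: reference sizes
    glia: GliaConfig | None = field(default_factory=GliaConfig)
    pretrain: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.005, epochs=30))
    finetune: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.3, momentum=0.9,
                                            epochs=150))
    seed: int = 0

    def resolved_sizes(self) -> tuple[int, ...]:
        if self.hidden_sizes is not None:
            return tuple(self.hidden_sizes)
        return TABLE_DBN_SIZES[self.subset]


def make_folds(n_instances: int, k: int, seed: int = 0, labels=None
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint test folds covering all indices (sizes differ by <= 1).

    Stratified on ``labels`` when every class has at least k members,
    otherwise plain seeded shuffling.
    """
    if k > n_instances:
        raise ValueError(f"k={k} exceeds n_instances={n_instances}")
    if k < 2:
        raise ValueError("k must be >= 2")
    X_dummy = np.zeros((n_instances, 1))
    if labels is not None:
        y = np.asarray(labels).reshape(-1)
        if np.min(np.bincount(y, minlength=2)) >= k:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            return [(tr, te) for tr, te in skf.split(X_dummy, y)]
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(X_dummy)]


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions."""
    y_true = np.asarray(y_true).reshape(-1)
    y_pred = np.asarray(y_pred).reshape(-1)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(skm.accuracy_score(y_true, y_pred))


def f1_score(y_true, y_pred, macro: bool = False) -> float:
    """Positive-class F1 (or macro-F1); 0 when precision + recall = 0."""
    y_true = np.asarray(y_true).reshape(-1)
    y_pred = np.asarray(y_pred).reshape(-1)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    avg = "macro" if macro else "binary"
    return float(skm.f1_score(y_true, y_pred, average=avg, pos_label=1,
                              zero_division=0))


@dataclass
class CVResult:
    """Per-subject, per-fold, per-dimension metrics with aggregation."""

    records: pd.DataFrame  # subject, fold, dimension, accuracy, f1, n_test

    def per_subject(self) -> pd.DataFrame:
        return (self.records
                .groupby(["subject", "dimension"], as_index=False)
                [["accuracy", "f1"]].mean())

    def aggregate(self) -> pd.DataFrame:
        """Mean/median/sd across subjects of their fold-averaged metrics."""
        per = self.per_subject()
        out = per.groupby("dimension").agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_median=("accuracy", "median"),
            accuracy_sd=("accuracy", "std"),
            f1_mean=("f1", "mean"),
            f1_median=("f1", "median"),
            f1_sd=("f1", "std"),
        )
        return out


def _fold_seed(seed: int, subject: int, dim: int, fold: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(subject, dim, fold))
               .generate_state(1)[0] % (2**31))


def _fit_predict(config, X_train, y_train, X_test, seed: int) -> np.ndarray:
    """Train one model on a fold and return hard test predictions."""
    if isinstance(config, EnsembleConfig):
        model = train_ensemble(X_train, y_train, config, seed=seed)
        _, pred = predict_ensemble(model, X_test)
        return pred
    if isinstance(config, DBNModelConfig):
        lo, hi = SUBSET_SLICES[config.subset]
        Xtr, Xte = X_train[:, lo:hi], X_test[:, lo:hi]
        sizes = (hi - lo, *config.resolved_sizes())
        dbn = DBNGC.build(sizes, seed=seed,
                          visible_type=config.pretrain.visible_type)
        pretrain(dbn, Xtr, replace(config.pretrain, seed=seed),
                 glia=config.glia)
        finetune(dbn, Xtr, y_train, replace(config.finetune, seed=seed))
        return predict_proba(dbn, Xte).argmax(axis=1)
    raise TypeError(f"unsupported model config: {type(config).__name__}")


def run_cv(features_by_subject, config, k: int = 10, seed: int = 0,
           strict_cv: bool = False, dimensions=(0, 1)) -> CVResult:
    """Subject-specific k-fold cross-validation.

    ``features_by_subject`` is a sequence of (X, Y) pairs: an instances
    by 664 feature matrix and an instances by 2 binary label matrix
    (arousal, valence) per subject.  For every subject and emotion
    dimension, folds are stratified on that dimension's labels, one
    model is trained per fold and accuracy / F1 are recorded.  With
    ``strict_cv`` standardization uses training-fold statistics only.
    """
    rows = []
    for s, (X, Y) in enumerate(features_by_subject):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=int)
        if X.shape[0] < k:
            raise ValueError(f"subject {s} has fewer instances than k={k}")
        if not strict_cv:
            Z_full, _, _ = standardize_subject(X)
        for d in dimensions:
            y = Y[:, d]
            folds = make_folds(X.shape[0], k, seed=_fold_seed(seed, s, d, 0),
                               labels=y)
            for f_idx, (tr, te) in enumerate(folds):
                if strict_cv:
                    Ztr, mu, sd = standardize_subject(X[tr])
                    Zte = apply_standardization(X[te], mu, sd)
                else:
                    Ztr, Zte = Z_full[tr], Z_full[te]
                if np.unique(y[tr]).size < 2:
                    continue  # degenerate fold: nothing to learn
                pred = _fit_predict(config, Ztr, y[tr], Zte,
                                    seed=_fold_seed(seed, s, d, f_idx + 1))
                rows.append({
                    "subject": s, "fold": f_idx, "dimension": DIMENSIONS[d],
                    "accuracy": accuracy(y[te], pred),
                    "f1": f1_score(y[te], pred),
                    "n_test": int(te.size),
                })
    return CVResult(records=pd.DataFrame(rows))


def evaluate_dataset(trials_by_subject, config, k: int = 10, seed: int = 0,
                     strict_cv: bool = False) -> CVResult:
    """Convenience wrapper: preprocess + extract features, then run CV."""
    feats = [extract_subject(trials) for trials in trials_by_subject]
    return run_cv(feats, config, k=k, seed=seed, strict_cv=strict_cv)


def compare_glia_variants(features_by_subject, subset: str = "F7",
                          hidden_sizes=None, glia: GliaConfig | None = None,
                          k: int = 10, seed: int = 0,
                          base_config: DBNModelConfig | None = None
                          ) -> pd.DataFrame:
    """Paired DBN vs DBN-GC comparison on one composite feature subset.

    Both variants share hyperparameters, folds and seeds; only the glia
    coupling differs.  Returns per-subject, per-dimension accuracy / F1
    rows tagged with the variant, ready for box-plot style comparison.
    """
    if base_config is None:
        base_config = DBNModelConfig(subset=subset, hidden_sizes=hidden_sizes)
    if glia is None:
        glia = GliaConfig()
    out = []
    for variant, g in (("dbn", None), ("dbn_gc", glia)):
        cfg = replace(base_config, subset=subset, glia=g)
        res = run_cv(features_by_subject, cfg, k=k, seed=seed)
        per = res.per_subject()
        per.insert(0, "variant", variant)
        out.append(per)
    return pd.concat(out, ignore_index=True)
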