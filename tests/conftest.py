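import numpy as np
import pytest

from gliadbn import (EnsembleConfig, FeatureSchema, SimConfig, TrainConfig,
                     extract_subject, simulate_subject)

#: Reduced branch layer sizes used for fast end-to-end runs.
SMALL_BRANCH_SIZES = {k: (32, 24, 16) for k in ("F1", "F2", "F3", "F4", "F5")}


def small_ensemble_config(**overrides) -> EnsembleConfig:
    """Ensemble config scaled down for desk-size experiments."""
    kwargs = dict(
        branch_sizes=SMALL_BRANCH_SIZES,
        fusion_hidden=16,
        pretrain=TrainConfig(learning_rate=0.005, epochs=10),
    )
    kwargs.update(overrides)
    return EnsembleConfig(**kwargs)


@pytest.fixture(scope="session")
def schema() -> FeatureSchema:
    return FeatureSchema.default()


@pytest.fixture(scope="session")
def subject_features():
    """Features of one strongly separable synthetic subject (seed 1).

    40 trials of 8 s, effect size 3: the class structure is recoverable
    by a linear rule, so model failures are attributable to the model.
    """
    cfg = SimConfig(n_subjects=1, n_trials_per_subject=40, duration=8.0,
                    effect_size=3.0, seed=1)
    X, Y = extract_subject(simulate_subject(cfg, 0))
    return X, Y


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
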