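import numpy as np
import pytest

from emossl import (
    GeneratorConfig,
    ModelConfig,
    TrainConfig,
    generate,
    split,
    standardize,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small standardized synthetic dataset shared across fast tests."""
    cfg = GeneratorConfig(
        n_clips=40, length_range=(40, 70), seed=123, signal_strength=2.0
    )
    ds = generate(cfg)
    split(ds, fraction=0.8, seed=1)
    ds, stats = standardize(ds)
    return ds, stats


@pytest.fixture()
def small_train_config():
    """Fast training config with a shrunken hidden size."""
    return TrainConfig(
        epochs=5,
        pretrain_epochs=3,
        seed=7,
        model=ModelConfig(hidden_size=24),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
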