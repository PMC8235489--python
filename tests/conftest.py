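import numpy as np
import pytest

from fgmi import BlockConfusionConfig, make_confusable_dataset


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated 5-class instance: every class mean ~20 sigma apart,
    so even a plain linear base model classifies it perfectly."""
    cfg = BlockConfusionConfig(
        n_classes=5, n_blocks=1, images_per_class=30, feature_dim=8,
        within_block_separation=20.0, between_block_separation=40.0,
        noise_sd=1.0, n_models=1, per_model_noise_sd=0.5, seed=3,
    )
    Xs, y, truth = make_confusable_dataset(cfg)
    return cfg, Xs, y, truth


@pytest.fixture(scope="session")
def confusable_dataset():
    """Default block-confusable instance (3 blocks of 4 overlapping classes)."""
    cfg = BlockConfusionConfig(seed=7)
    Xs, y, truth = make_confusable_dataset(cfg)
    return cfg, Xs, y, truth
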