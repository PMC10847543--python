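"""Shared fixtures: phantom sets and the session-scoped smoke-trained model."""

from __future__ import annotations

import numpy as np
import pytest

from echonac.losses import LossWeights
from echonac.model import SegModelConfig, build_model
from echonac.phantom import phantom_training_set
from echonac.training import TrainConfig, train

SMOKE_DIMS = (128, 96)
SMOKE_SEED = 7
SMOKE_N_IMAGES = 200
SMOKE_EPOCHS = 14


def smoke_model_config(variant: str = "full", dims=SMOKE_DIMS,
                       seed: int = SMOKE_SEED) -> SegModelConfig:
    """CPU-scale architecture used for all training experiments in the suite."""
    return SegModelConfig(variant=variant, depth=3, base_channels=8,
                          aspp_rates=(1, 2, 4), input_size=dims, seed=seed)


@pytest.fixture(scope="session")
def smoke_phantoms():
    pairs = phantom_training_set(SMOKE_N_IMAGES, dims=SMOKE_DIMS, seed=SMOKE_SEED)
    return [(img.pixels, mask) for img, mask in pairs]


@pytest.fixture(scope="session")
def smoke_split(smoke_phantoms):
    n_val = SMOKE_N_IMAGES // 5
    return smoke_phantoms[:-n_val], smoke_phantoms[-n_val:]


@pytest.fixture(scope="session")
def smoke_trained(smoke_split):
    """Full-variant network trained once on the smoke phantom set."""
    train_set, val_set = smoke_split
    net = build_model(smoke_model_config())
    config = TrainConfig(epochs=SMOKE_EPOCHS, input_size=SMOKE_DIMS, seed=SMOKE_SEED)
    net, history = train(net, train_set, val_set, LossWeights(), config)
    return net, history


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
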