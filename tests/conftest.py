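"""Shared fixtures: tiny synthetic cohorts and small trained models.

The trained-model fixtures are deliberately small (16x16 images, width-4
network, a handful of epochs) so the whole suite runs on one CPU in a few
minutes; the full desk-scale experiment lives in the acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from gaseg.synthetic import SyntheticConfig, generate_dataset
from gaseg.train import AugmentConfig, TrainConfig, train_model
from gaseg.unet import ModelConfig, UNet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


TOY_SYN = dict(image_height=16, image_width=16, n_lesions_range=(1, 2),
               lesion_radius_range=(2.5, 5.0), grader_boundary_sd=1.0,
               grader_satellite_flip_prob=0.2)


@pytest.fixture(scope="session")
def toy_dataset():
    cfg = SyntheticConfig(**TOY_SYN, seed=11)
    return generate_dataset(cfg, 12)


def _train_toy(variant: str, dataset, seed: int) -> UNet:
    model = UNet(ModelConfig(base_channels=4, variant=variant), seed=seed)
    cfg = TrainConfig(initial_lr=1e-3, epochs=12, batch_size=2, seed=seed,
                      augmentation=AugmentConfig.identity())
    train_model(model, dataset[:8], dataset[8:], cfg)
    return model


@pytest.fixture(scope="session")
def toy_model(toy_dataset):
    """A small standard-variant model trained enough to be non-degenerate."""
    return _train_toy("standard", toy_dataset, seed=21)


@pytest.fixture(scope="session")
def toy_drop_model(toy_dataset):
    """A small drop-variant model for MC-dropout tests."""
    return _train_toy("drop", toy_dataset, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
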