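"""Shared fixtures: tiny synthetic datasets and a quickly trained projector.

Everything is generated at test time from fixed seeds; the heavier trained
models are session-scoped so several test modules can share them.
"""

import numpy as np
import pytest

from lsproj import (ImageGenConfig, TabularGenConfig, NetworkSpec, LSPModel,
                    TrainingConfig, build_decoder, build_discriminator,
                    build_encoder, generate_images, generate_transactions,
                    train_lsp)


@pytest.fixture(scope="session")
def small_images():
    """600 16x16 images, uncorrelated label/attribute, fixed seed."""
    return generate_images(ImageGenConfig(
        n_samples=600, image_size=16, label_attr_correlation=0.0,
        noise_sd=0.05, seed=11))


@pytest.fixture(scope="session")
def small_table():
    """5000-row transaction table with a 10% positive rate (dense enough
    for classifier tests)."""
    return generate_transactions(TabularGenConfig(
        n_samples=5000, n_features=10, fraud_rate=0.1, seed=5))


def train_tiny_image_model(data, gamma, seed=3, epochs=6):
    spec = NetworkSpec("image", data.X.shape[1:])
    model = LSPModel(build_encoder(spec, seed), build_decoder(spec, seed + 1),
                     spec, seed=seed)
    disc = build_discriminator(spec, seed + 2)
    config = TrainingConfig(gamma=gamma, epochs=epochs, seed=seed)
    return train_lsp(model, disc, data, config)


@pytest.fixture(scope="session")
def trained_autoencoder(small_images):
    """gamma=0 run on the small image set (plain autoencoder + routing)."""
    return train_tiny_image_model(small_images, gamma=0.0)


@pytest.fixture(scope="session")
def trained_adversarial(small_images):
    """gamma=2 run on the same data and seeds."""
    return train_tiny_image_model(small_images, gamma=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
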