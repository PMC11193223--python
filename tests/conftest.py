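"""Shared fixtures: phantom dataset, trained CNN fixture, toy models.

The trained fixture is session-scoped (one ~45 s training run shared by all
tests that need a model with meaningful gradients); everything is seeded so
the suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from medsal import (
    CNNModelHandle,
    LinearModelHandle,
    PhantomConfig,
    generate_phantoms,
    train_fixture_cnn,
)
from medsal.nn import SmallCNN

# study conditions: 1200 training + 300 held-out phantoms, 64x64,
# noise sigma 0.05, lesion contrast 0.6
STUDY_CONFIG = PhantomConfig(
    n_samples=1500, image_size=64, noise_sigma=0.05, lesion_contrast=0.6, seed=7
)


@pytest.fixture(scope="session")
def phantoms():
    return generate_phantoms(STUDY_CONFIG)


@pytest.fixture(scope="session")
def train_samples(phantoms):
    return phantoms[:1200]


@pytest.fixture(scope="session")
def holdout_samples(phantoms):
    return phantoms[1200:]


@pytest.fixture(scope="session")
def fixture_model(train_samples) -> CNNModelHandle:
    return train_fixture_cnn(train_samples, epochs=6, seed=0)


@pytest.fixture(scope="session")
def tiny_model() -> CNNModelHandle:
    """Small untrained CNN (32x32) for fast structural/gradient tests."""
    return CNNModelHandle(SmallCNN(image_shape=(32, 32, 1), seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_image(rng):
    return rng.uniform(0.2, 0.8, size=(32, 32, 1))


@pytest.fixture()
def linear_model(rng) -> LinearModelHandle:
    """3-class linear scorer on 8x8 grayscale images."""
    return LinearModelHandle(rng.normal(size=(3, 8, 8, 1)))


def duplicate_channel_reparam(handle: CNNModelHandle) -> CNNModelHandle:
    """Functionally identical CNN with every last-conv channel split in two.

    Each third-block channel is duplicated and the dense weights halved, so
    the two architectures (16 vs 32 channels) compute bit-equal logits —
    the implementation-invariance construction.
    """
    net = handle.net
    H, W, C = net.image_shape
    c1, c2, c3 = net.channels
    twin = SmallCNN(image_shape=(H, W, C), num_classes=net.num_classes,
                    channels=(c1, c2, 2 * c3), seed=net.seed)
    params = {name: (layer, key) for name, layer, key, _ in twin.named_params()}
    src = {name: arr for name, _, _, arr in net.named_params()}
    for name in ("conv1_pre.W", "conv1_pre.b", "conv2_pre.W", "conv2_pre.b"):
        layer, key = params[name]
        getattr(layer, key)[...] = src[name]
    conv3 = params["conv3_pre.W"][0]
    conv3.W[...] = np.repeat(src["conv3_pre.W"], 2, axis=-1)
    conv3.b[...] = np.repeat(src["conv3_pre.b"], 2)
    dense = params["dense.W"][0]
    wd = src["dense.W"].reshape((H // 8) * (W // 8), c3, net.num_classes)
    dense.W[...] = np.repeat(wd, 2, axis=1).reshape(-1, net.num_classes) / 2.0
    dense.b[...] = src["dense.b"]
    return CNNModelHandle(twin)
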