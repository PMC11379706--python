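import numpy as np
import pytest

from myth.model_core import LabeledImage, TrainConfig, build_model
from myth.synthdata import WorldSpec, generate_dataset

TINY_SHAPE = (16, 16, 1)


@pytest.fixture(scope="session")
def tiny_model():
    """Small model on 16x16 inputs (2x2 latent grid)."""
    return build_model(TINY_SHAPE, depth=6, per_class=2, n_classes=2, seed=7)


@pytest.fixture(scope="session")
def tiny_world():
    return WorldSpec(height=16, width=16, feature_contrast=0.5, noise_sd=0.05,
                     n_per_class=12, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_world):
    return generate_dataset(tiny_world)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_image(rng, shape=TINY_SHAPE, label=0, image_id="x"):
    return LabeledImage(rng.uniform(0.0, 1.0, shape), label, image_id)


@pytest.fixture()
def fast_cfg():
    return TrainConfig(epochs=2, batch_size=8, seed=0)
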