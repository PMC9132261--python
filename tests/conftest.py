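import numpy as np
import pytest

from ssimcut import ModelSpec, SyntheticConfig, build_model, generate


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 12 images at 32x32 — enough for fast training tests."""
    return generate(SyntheticConfig(class_count=3, images_per_class=12,
                                    image_size=32, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study fixture: 3 classes x 100 images at 64x64."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture
def tiny_net():
    """Seeded 4-conv shallow model on 32x32 inputs."""
    return build_model(ModelSpec(family="shallow", conv_layers=4,
                                 input_size=32, class_count=3, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
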