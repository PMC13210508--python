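import numpy as np
import pytest

from persal import synth
from persal.model import PsmModelConfig


@pytest.fixture(scope="session")
def tiny_world():
    """4 subjects x 12 images at 128x128: small enough for model training."""
    return synth.generate_world(
        n_subjects=4, n_images=12, image_size=(128, 128), seed=3
    )


@pytest.fixture(scope="session")
def tiny_corpus(tiny_world):
    """Full fixture set at 1/4 map scale (32x32 maps and stimuli)."""
    return synth.build_corpus(tiny_world, map_scale=0.25)


@pytest.fixture
def tiny_cfg():
    """Desk-scale model config: 32x32 input, 1/16 width (C=32), 4 heads."""
    return PsmModelConfig(
        input_size=(32, 32), channel_scale=1 / 16, M=12,
        enc_layers=1, dec_layers=1, heads=4, seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
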