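import numpy as np
import pytest

from beast import SceneConfig, generate_scene
from beast.backbone import EncoderConfig, VisionTransformer


@pytest.fixture(scope="session")
def small_scene():
    """A short 3-state scene shared by read-only tests."""
    return generate_scene(SceneConfig(n_frames=200, seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    """A very small encoder for fast unit tests (32px frames, 16 patches)."""
    return EncoderConfig(image_size=32, P=8, D=32, depth=2, heads=2,
                         decoder_width=16, decoder_depth=1,
                         projector_hidden=32, projector_out=16, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return VisionTransformer(tiny_config)


@pytest.fixture(scope="session")
def tiny_scene():
    """32px scene matching the tiny encoder."""
    return generate_scene(SceneConfig(image_height=32, image_width=32,
                                      sprite_radius=5.0, n_frames=200, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
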