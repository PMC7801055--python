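import numpy as np
import pytest

from ffunet import ModelConfig, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest legal network: fast enough for per-test forward/backward."""
    return ModelConfig(depth=2, base_channels=9)


@pytest.fixture
def small_synth_config():
    return SynthConfig(image_height=128, image_width=128, seed=7)
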