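import numpy as np
import pytest

from stholter.ebtnet import ModelConfig


@pytest.fixture
def tiny_config() -> ModelConfig:
    """Smallest two-stage geometry (window 4) for fast structural tests."""
    return ModelConfig(input_length=16, window_size=4, stage_depths=(3, 3),
                       stage_channels=(4, 8), stage_heads=(2, 2))


@pytest.fixture
def toy_config() -> ModelConfig:
    """Desk-scale geometry with the full-size window (112)."""
    return ModelConfig(input_length=448, window_size=112, stage_depths=(3, 3),
                       stage_channels=(8, 16), stage_heads=(2, 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
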