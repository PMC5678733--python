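import numpy as np
import pytest

from astromap import ModelConfig, SheetGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    return SheetGeometry(extent=1.0, density=16)


@pytest.fixture
def tiny_config():
    """A deliberately small model configuration for fast unit tests."""
    return ModelConfig(density=16, seed=7)
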