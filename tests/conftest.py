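import numpy as np
import pytest

from hacrnet.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Smallest structurally complete model: C=4, one CAAM, x2."""
    return ModelConfig(
        base_channels=4,
        caam_count=1,
        scale=2,
        ca_reduction=2,
        sa_reduction=2,
        crab_width=2,
        seed=7,
    )


@pytest.fixture
def small_cfg():
    """A slightly wider model exercising non-trivial attention widths."""
    return ModelConfig(
        base_channels=8,
        caam_count=2,
        scale=2,
        ca_reduction=4,
        sa_reduction=2,
        crab_width=5,
        seed=3,
    )
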