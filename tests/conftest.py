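import numpy as np
import pytest

from idolseg.fcd_net import NetConfig
from idolseg.phantom import PhantomConfig, generate_case


@pytest.fixture(scope="session")
def tiny_net_cfg() -> NetConfig:
    """Smallest sensible network: one down block + bottleneck."""
    return NetConfig(
        dense_block_layers=(1, 2), growth_rate=4, dropout_rate=0.0, first_conv_channels=8
    )


@pytest.fixture(scope="session")
def tiny_phantom_cfg() -> PhantomConfig:
    """Small coarse phantom for fast training tests (24x24x8 voxels)."""
    return PhantomConfig(
        shape=(24, 24, 8),
        spacing=(2.8, 2.8, 8.0),
        liver_semiaxes=(24.0, 20.0, 26.0),
        tumor_n_lobes=1,
        tumor_semiaxes_range=(8.0, 12.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_case(tiny_phantom_cfg):
    case, truth = generate_case(tiny_phantom_cfg, "tiny")
    return case, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
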