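import numpy as np
import pytest

from cycledeblur import autodiff as ad
from cycledeblur.networks import (DiscriminatorConfig, GeneratorConfig,
                                  build_networks)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_nets():
    """Smallest valid network set; shared where tests only read them."""
    gen_cfg = GeneratorConfig(base_channels=4, n_residual_blocks=1)
    disc_cfg = DiscriminatorConfig(channels=(8, 16, 32), strides=(2, 2, 2))
    return build_networks(gen_cfg, disc_cfg, seed=7)


@pytest.fixture()
def float64_engine():
    """Run the autodiff engine in float64 for tight numerical comparisons."""
    old = ad.DTYPE
    ad.DTYPE = np.float64
    ad.clear_scratch()
    yield
    ad.DTYPE = old
    ad.clear_scratch()
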