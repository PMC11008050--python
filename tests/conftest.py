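import numpy as np
import pytest

from dmfit import DMFParameters, SyntheticConfig, calibrate_fic, gen_atrophy_map, gen_connectome


@pytest.fixture(scope="session")
def small_cfg():
    """Small synthetic study used by fast unit tests."""
    return SyntheticConfig(n_regions=16, connectome_density=0.4, atrophy_focus=tuple(range(4, 9)), seed=7)


@pytest.fixture(scope="session")
def small_connectome(small_cfg):
    return gen_connectome(small_cfg)


@pytest.fixture(scope="session")
def small_atrophy(small_cfg):
    return gen_atrophy_map(small_cfg, "AD")


@pytest.fixture(scope="session")
def short_params():
    return DMFParameters(t_total=20.0, t_burn=2.0)


@pytest.fixture(scope="session")
def small_J0(short_params, small_connectome):
    return calibrate_fic(short_params, small_connectome, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
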