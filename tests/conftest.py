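import numpy as np
import pytest

from alanphen.models import ModelParams, SenescenceModelSpec
from alanphen.synthetic import SyntheticConfig, generate_site_dataset, simulate_observed_dfs


@pytest.fixture(scope="session")
def base_config():
    return SyntheticConfig(n_sites=3, seed=11)


@pytest.fixture(scope="session")
def site(base_config):
    return generate_site_dataset(base_config, 0)


@pytest.fixture(scope="session")
def cdd_spec():
    return SenescenceModelSpec("CDD")


@pytest.fixture(scope="session")
def cdd_params(cdd_spec):
    return ModelParams(cdd_spec, {"t_th": 22.0, "cdd_th": 120.0})


@pytest.fixture(scope="session")
def cdd_site(site, cdd_spec, cdd_params):
    """Site with noise-free observed DFS generated by a known CDD model."""
    return simulate_observed_dfs(site, cdd_spec, cdd_params, 0.0, seed=5)


def synthetic_temp_year(post_solstice, fill=30.0):
    """365-day temperature series: `fill` everywhere, the given values
    starting at the solstice (DOY 172)."""
    temp = np.full(365, fill)
    temp[171 : 171 + len(post_solstice)] = post_solstice
    return temp
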