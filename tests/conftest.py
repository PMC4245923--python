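import numpy as np
import pytest

from hlarray import (
    SimConfig,
    build_probe_set,
    generate_allele_catalog,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=101)


@pytest.fixture(scope="session")
def sim_catalog(sim_config):
    catalog, serogroups = generate_allele_catalog(sim_config)
    return catalog, serogroups


@pytest.fixture(scope="session")
def sim_probeset(sim_catalog):
    catalog, _ = sim_catalog
    return build_probe_set(catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
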