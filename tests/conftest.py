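import numpy as np
import pytest

from saltol import SyntheticConfig, generate_trait_table


@pytest.fixture(scope="session")
def small_table():
    """A 60-accession synthetic trial (120 rows) shared across tests."""
    return generate_trait_table(SyntheticConfig(n_accessions=60, seed=11))


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
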