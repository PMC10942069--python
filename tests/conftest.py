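import pytest

from trastcea import basecase_config_path, load_config, reference_lifetable_path
from trastcea.analysis import run_psa_model
from trastcea.markov import LifeTable

SEED = 20240315


@pytest.fixture(scope="session")
def params():
    return load_config(basecase_config_path())


@pytest.fixture(scope="session")
def lifetable():
    return LifeTable.from_tsv(reference_lifetable_path())


@pytest.fixture(scope="session")
def psa_draws(params, lifetable):
    """Full-size PSA on the bundled base case (shared across tests)."""
    return run_psa_model(params, lifetable, 10_000, seed=SEED)
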