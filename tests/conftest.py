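import pytest

from polyprospect.cassette_mining import MiningConfig
from polyprospect.homology import default_scheme
from polyprospect.synthetic_data import make_role_queries


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def role_queries():
    return make_role_queries(seed=1)


@pytest.fixture(scope="session")
def mining_config():
    return MiningConfig()
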