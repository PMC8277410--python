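import numpy as np
import pytest

from chdi import ScoringConfig, default_fixture, run_pipeline


@pytest.fixture(scope="session")
def fixture_data():
    """The packaged 310-hospital synthetic table and its ground truth."""
    return default_fixture(seed=2021)


@pytest.fixture(scope="session")
def fixture_table(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_truth(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def default_config():
    return ScoringConfig(seed=2021)


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_table, default_config):
    """One full scoring run on the default fixture, shared across tests."""
    return run_pipeline(fixture_table, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
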