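import numpy as np
import pytest

from mvddi import default_fixture, unified_features_from_tables


@pytest.fixture(scope="session")
def fixture_data():
    """The standard 120-drug / 8-class synthetic fixture (seed 7)."""
    tables, dataset, truth = default_fixture(seed=7)
    return tables, dataset, truth


@pytest.fixture(scope="session")
def fixture_x(fixture_data):
    tables, _, _ = fixture_data
    return unified_features_from_tables(tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
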