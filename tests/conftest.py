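import numpy as np
import pytest

from mtburden import reference
from mtburden.examples import table1_marginal_cohort


@pytest.fixture(scope="session")
def region_map():
    return reference.build_region_map()


@pytest.fixture(scope="session")
def rcrs():
    return reference.load_sequence()


@pytest.fixture(scope="session")
def table1_cohort():
    """(clinical, calls) fixture matching the printed cohort marginals."""
    return table1_marginal_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
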