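import numpy as np
import pytest

from mockbench.community_model import MockCommunity, TaxonSpec, expected_proportions
from mockbench.datasets import load_default_community


@pytest.fixture(scope="session")
def community():
    return load_default_community()


@pytest.fixture(scope="session")
def expected(community):
    return expected_proportions(community)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_community():
    return MockCommunity(
        (
            TaxonSpec("alpha", 1, 2.0),
            TaxonSpec("beta", 2, 1.0),
            TaxonSpec("gamma", 2, 1.0),
        )
    )
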