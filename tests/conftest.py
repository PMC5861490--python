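import pytest

from vitring.idsearch import build_index
from vitring.simdata import make_mock_community, simulate_reads


@pytest.fixture(scope="session")
def mock_community():
    """Ten K2P-diverged species, copy numbers 1..10, known molarities."""
    return make_mock_community(n_species=10, seed=42)


@pytest.fixture(scope="session")
def mock_refs(mock_community):
    return [sp.record for sp in mock_community.species]


@pytest.fixture(scope="session")
def mock_index(mock_refs):
    return build_index(mock_refs, k=16)


@pytest.fixture(scope="session")
def mock_reads(mock_community):
    """300 error-free reads with their truth table."""
    return simulate_reads(mock_community, 300, seed=7)
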