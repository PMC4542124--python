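import pytest

from mosaictox.models import SubstitutionModel
from mosaictox.seq_core import Genome


@pytest.fixture
def toy_genome() -> Genome:
    return Genome(id="toy", sequence="ACGTACGGCCAATTGGCCGGAACCTTGG" * 10)


@pytest.fixture
def balanced_tree() -> str:
    """Four-taxon tree with a well-supported inner edge."""
    return "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);"


@pytest.fixture
def conflicting_tree() -> str:
    """Alternative topology pairing A with C."""
    return "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);"


@pytest.fixture
def hky() -> SubstitutionModel:
    return SubstitutionModel("HKY85", kappa=4.0)
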