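import pytest

from paleodup.simulate import make_reference_chronogram
from paleodup.trees import read_newick


@pytest.fixture(scope="session")
def chronogram():
    return make_reference_chronogram()


@pytest.fixture(scope="session")
def balanced8_coalescent_tree():
    """8-taxon species tree with moderate coalescent-unit branches:
    short internals generate real ILS discordance."""
    return read_newick(
        "(((A:1,B:1):0.5,(C:0.8,D:0.8):0.7):0.5,"
        "((E:1.2,F:1.2):0.3,(G:0.6,H:0.6):0.9):0.5):5;"
    )
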