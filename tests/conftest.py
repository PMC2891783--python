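import numpy as np
import pytest

from treecarto.tree_core import TaxonMap, Split, read_newick, enumerate_trees


@pytest.fixture(scope="session")
def taxa5():
    return TaxonMap([str(i) for i in range(1, 6)])


@pytest.fixture(scope="session")
def tree5(taxa5):
    return read_newick("((1,2),3,(4,5));", taxa5)


@pytest.fixture(scope="session")
def all_trees5(taxa5):
    return list(enumerate_trees(5, taxa5))


@pytest.fixture(scope="session")
def all_trees6():
    return list(enumerate_trees(6))


def split5(*one_based):
    """Split of n=5 from 1-based taxon numbers (labels '1'..'5')."""
    return Split.from_indices({i - 1 for i in one_based}, 5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100608)
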