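import pytest

from mirmeta.dollo import SpeciesTree
from mirmeta.simulate import DEFAULT_TREE_NEWICK, SimulationConfig


@pytest.fixture(scope="session")
def default_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture(scope="session")
def four_leaf_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("((A,B)AB,(C,D)CD)Root;")


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=1, n_families=20, n_reads=500)
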