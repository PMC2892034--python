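import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

from cyprodent.formulae import build_character_matrix, load_species_table
from cyprodent.simulate import yule_tree
from cyprodent.trees import load_fig5_tree


@pytest.fixture(scope="session")
def records():
    return load_species_table()


@pytest.fixture(scope="session")
def matrix(records):
    return build_character_matrix(records)


@pytest.fixture()
def fig5_unit():
    return load_fig5_tree("unit")


def random_instance(rng: np.random.Generator, n_tips: int, k: int, missing: bool = True):
    """A small random tree with random branch lengths plus random tip states.

    Returns (tree, tips, states).  Branch lengths are redrawn uniformly so
    instances are not ultrametric; with ``missing`` about 20% of tips are
    unscored.
    """
    states = tuple("ABC"[:k])
    tree = yule_tree(n_tips, 1.0, rng)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.05, 2.0))
    tips = {}
    for leaf in tree.leaf_node_iter():
        if missing and rng.random() < 0.2:
            tips[leaf.taxon.label] = "?"
        else:
            tips[leaf.taxon.label] = states[int(rng.integers(k))]
    return tree, tips, states
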