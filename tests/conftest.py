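import dendropy
import numpy as np
import pytest

from macrosem import GridSpec, build_weights


def tree_from_newick(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="default-rooted")


@pytest.fixture
def balanced_tree():
    """Balanced 4-tip tree, all edges length 1."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_tree():
    """Caterpillar (A:3,(B:2,(C:1,D:1):1):1)."""
    return tree_from_newick("(A:3,(B:2,(C:1,D:1):1):1);")


@pytest.fixture
def grid9():
    return GridSpec(3, 3, 100.0)


@pytest.fixture
def grid400():
    return GridSpec(20, 20, 100.0)


@pytest.fixture
def weights400(grid400):
    return build_weights(grid400, scheme="queen")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
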