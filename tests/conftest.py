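import numpy as np
import pytest

import rategls as rg


@pytest.fixture
def tree2():
    """Two-tip star of unit height."""
    return rg.read_newick("(A:1,B:1);")


@pytest.fixture
def tree3():
    """Three tips: cherry (A,B) at depth 0.5 plus outgroup C."""
    return rg.read_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def tree5():
    """Five tips with nested structure, unit height."""
    return rg.read_newick(
        "(((A:0.2,B:0.2):0.3,C:0.5):0.5,(D:0.7,E:0.7):0.3);"
    )


@pytest.fixture
def T3(tree3):
    return rg.shared_branch_matrix(tree3).T


@pytest.fixture
def T5(tree5):
    return rg.shared_branch_matrix(tree5).T


@pytest.fixture(scope="session")
def fixture_tree_50():
    return rg.make_fixture_tree(50, seed=2024)


@pytest.fixture(scope="session")
def fixture_tree_200():
    return rg.make_fixture_tree(200, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
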