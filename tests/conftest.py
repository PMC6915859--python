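import pytest

from tcnet.netcore import PhyloNetwork, base_network
from tcnet.rearrange import leaf_insert, ret_insert


@pytest.fixture
def base1():
    return base_network(1)


@pytest.fixture
def base2():
    return base_network(2)


@pytest.fixture
def cherry3(base2):
    """The tree ((1,2),3): taxon 3 attached to the root edge of base2."""
    return leaf_insert(base2, (0, 1), 3)


@pytest.fixture
def ret12(base1):
    """Same-edge reticulation insertion into the one-taxon tree: the member
    of TCN_1(2) whose reticulation parents are comparable (not normal)."""
    return ret_insert(base1, (0, 1), (0, 1), 2)


@pytest.fixture
def non_tree_child():
    """A valid rooted binary network on {1,2} that is not tree-child:
    two tree nodes whose children are both reticulate."""
    N = PhyloNetwork()
    root = N.new_node()
    a = N.new_node()
    b = N.new_node()
    c = N.new_node()
    r1 = N.new_node()
    r2 = N.new_node()
    l1 = N.new_node()
    l2 = N.new_node()
    N.root = root
    for u, v in [(root, a), (a, b), (a, c), (b, r1), (b, r2),
                 (c, r1), (c, r2), (r1, l1), (r2, l2)]:
        N.add_edge(u, v)
    N.set_leaf_label(l1, 1)
    N.set_leaf_label(l2, 2)
    return N
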