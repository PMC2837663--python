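import dendropy
import numpy as np
import pytest

# fixed 5-leaf fixture with hand-set branch lengths; internal nodes labelled
FIVE_LEAF_NEWICK = (
    "((A:0.30,B:0.20)i2:0.10,(C:0.15,(D:0.05,E:0.25)i4:0.20)i3:0.30)i1;"
)


@pytest.fixture
def five_leaf_tree():
    return dendropy.Tree.get(data=FIVE_LEAF_NEWICK, schema="newick")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            counter += 1
            if node.label in (None, ""):
                node.label = f"i{counter:04d}"
    return tree
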