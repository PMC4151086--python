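import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bqsnet import GRN


def tf_grn(edges, nodes=None):
    """GRN whose nodes are all designated TFs (analysis sees every edge)."""
    node_set = {x for e in edges for x in e}
    if nodes:
        node_set |= set(nodes)
    return GRN(edges, tf_set=node_set)


@pytest.fixture
def triangle():
    return tf_grn([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def chain():
    return tf_grn([("A", "B"), ("B", "C")])


@pytest.fixture
def two_triangles_disjoint():
    return tf_grn(
        [("A", "B"), ("B", "C"), ("C", "A"),
         ("D", "E"), ("E", "F"), ("F", "D")]
    )


@pytest.fixture
def two_triangles_shared_edge():
    # triangles A->B->C->A and A->B->D->A share edge A->B
    return tf_grn(
        [("A", "B"), ("B", "C"), ("C", "A"), ("B", "D"), ("D", "A")]
    )
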