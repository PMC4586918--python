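import numpy as np
import pytest

from swcedit import SwcNode, SwcTree, set_parent


def build_tree(spec):
    """Build a tree from ``(id, parent, (x, y, z), radius)`` rows.

    Children attach in row order via the validity-preserving
    ``set_parent``, which prepends: to get sibling chains in row order
    the rows for one parent are attached in reverse.  The returned tree
    has a fresh (empty) journal.
    """
    tree = SwcTree()
    for nid, _parent, center, radius in spec:
        tree.add(SwcNode(nid, 3, center, radius))
    by_parent = {}
    for nid, parent, _c, _r in spec:
        if parent is not None:
            by_parent.setdefault(parent, []).append(nid)
    for parent, kids in by_parent.items():
        for nid in reversed(kids):
            set_parent(tree, nid, parent)
    tree.journal = None
    return tree


@pytest.fixture
def make_tree():
    return build_tree


@pytest.fixture
def chain5():
    """A straight five-node chain along x."""
    return build_tree([(i, i - 1 if i > 1 else None, (float(i - 1), 0.0, 0.0), 1.0)
                       for i in range(1, 6)])


@pytest.fixture
def y_tree():
    """Root -> stem -> two leaves: one branch point, three termini."""
    return build_tree([
        (1, None, (0.0, 0.0, 0.0), 1.0),
        (2, 1, (1.0, 0.0, 0.0), 1.0),
        (3, 2, (2.0, 1.0, 0.0), 1.0),
        (4, 2, (2.0, -1.0, 0.0), 1.0),
    ])
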