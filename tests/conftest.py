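import warnings

import numpy as np
import pytest

from dendrodomains import (
    DendriteTree,
    TreePosition,
    classify_high_activity,
    compute_frequencies,
    filter_active,
    generate_cohort,
)

warnings.filterwarnings("ignore", message=".*degenerate.*")


@pytest.fixture
def line_tree():
    """Unbranched 100 µm dendrite; positions live on edge 2."""
    return DendriteTree.line(100.0)


@pytest.fixture
def y_tree():
    """Y-shaped tree: 20 µm trunk, branch point at node 2, children of
    lengths 25 and 7 µm (edges 3 and 4)."""
    return DendriteTree(
        nodes={1: (0, 0, 0), 2: (20, 0, 0), 3: (45, 0, 0), 4: (20, 7, 0)},
        edges=[(1, 2), (2, 3), (2, 4)],
        root=1,
    )


def random_tree(rng, n_nodes=8, max_len=30.0):
    """Random rooted geometric tree with uniform edge lengths."""
    nodes = {1: (0.0, 0.0, 0.0)}
    edges = []
    lengths = {}
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        length = float(rng.uniform(2.0, max_len))
        nodes[i] = (rng.uniform(-50, 50), rng.uniform(-50, 50), 0.0)
        edges.append((parent, i))
        lengths[i] = length
    return DendriteTree(nodes, edges, root=1, lengths=lengths)


def random_position(tree, rng):
    e = tree.edges[int(rng.integers(len(tree.edges)))]
    return TreePosition(e, float(rng.uniform(0, tree.edge_length[e])))


@pytest.fixture(scope="session")
def classified_cohort():
    """20 synthetic dendrites (10 young + 10 old) carried through frequency
    computation, the functional filter and high-activity classification."""
    cohort = generate_cohort(seed=1, n_per_group=10)
    exps = [e for e, _ in cohort]
    for e in exps:
        compute_frequencies(e)
        e.synapses = filter_active(e.synapses)
    classify_high_activity(exps)
    return cohort
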