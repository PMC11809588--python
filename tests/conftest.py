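import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from coalmorph.tree import PhyloTree


@pytest.fixture
def triplet_tree() -> PhyloTree:
    return PhyloTree.from_newick(
        "((A:1,B:1):0.5,C:1.5);", length_unit="coalescent_units"
    )


@pytest.fixture
def quartet_tree() -> PhyloTree:
    return PhyloTree.from_newick(
        "((A:0.3,B:0.2):0.15,(C:0.4,D:0.1):0.25);", length_unit="subst_per_site"
    )


def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random binary rooted tree with Exp(1)-ish branch lengths."""
    parent = [-1]
    lengths = [0.0]
    active = []
    for _ in range(2):
        parent.append(0)
        lengths.append(float(rng.uniform(0.05, 1.2)))
        active.append(len(parent) - 1)
    while len(active) < n_leaves:
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            parent.append(split)
            lengths.append(float(rng.uniform(0.05, 1.2)))
            active.append(len(parent) - 1)
    labels = [None] * len(parent)
    for i, node in enumerate(active):
        labels[node] = f"t{i}"
    return PhyloTree(parent, lengths, labels, length_unit="subst_per_site")
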