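import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from paeml import AreaTree, TaxonAreaMatrix


@pytest.fixture
def quartet_tree() -> AreaTree:
    return AreaTree.from_newick("((A:0.3,B:0.2):0.15,(C:0.25,D:0.4):0.1);")


@pytest.fixture
def quartet_matrix() -> TaxonAreaMatrix:
    return TaxonAreaMatrix(
        ["A", "B", "C", "D"],
        ["s1", "s2", "s3", "s4"],
        [[1, 0, 1, 1], [1, 0, 0, 1], [0, 1, 0, 1], [0, 1, 1, 1]],
    )


def random_matrix(rng: np.random.Generator, n_areas: int, n_chars: int,
                  names=None) -> TaxonAreaMatrix:
    names = names or [chr(ord("A") + i) for i in range(n_areas)]
    cells = rng.integers(0, 2, size=(n_areas, n_chars))
    return TaxonAreaMatrix(names, [f"s{j}" for j in range(n_chars)], cells)


def random_tree(rng: np.random.Generator, labels: list[str],
                min_len=0.05, max_len=0.8) -> AreaTree:
    """Random resolved topology with random branch lengths."""
    from oracles import all_unrooted_topologies

    tops = all_unrooted_topologies(labels)
    tree = tops[int(rng.integers(len(tops)))]
    for e in tree.dendropy_tree.preorder_edge_iter():
        if e.head_node is not tree.dendropy_tree.seed_node:
            e.length = float(rng.uniform(min_len, max_len))
    return tree
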