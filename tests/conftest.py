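from pathlib import Path

import numpy as np
import pytest

from spectral_supertree import RootedTree, parse_newick
from spectral_supertree.tree import TreeNode

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def fixtures_dir() -> Path:
    return FIXTURES


def random_resolved_tree(labels, rng: np.random.Generator) -> RootedTree:
    """A uniformly-joined random rooted bifurcating tree on ``labels``."""
    nodes = [TreeNode(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b]))
    return RootedTree(nodes[0], validate=False)


def random_tree_with_lengths(labels, rng: np.random.Generator) -> RootedTree:
    tree = random_resolved_tree(labels, rng)
    for node in tree.iter_nodes():
        if node is not tree.root:
            node.length = float(rng.uniform(0.05, 2.0))
    tree._index()
    return tree


def displays(supertree: RootedTree, source: RootedTree) -> bool:
    """True iff the supertree displays the source tree (the source is
    obtainable from the induced supertree by contractions)."""
    induced = supertree.induce(source.taxa)
    if induced is None or induced.taxa != source.taxa:
        return False
    return source.clade_set().clades <= induced.clade_set().clades


def displayed_triples(tree: RootedTree) -> set:
    """All rooted triples ab|c displayed by the tree."""
    taxa = sorted(tree.taxa)
    out = set()
    from itertools import combinations

    for a, b, c in combinations(taxa, 3):
        for pair, outsider in (((a, b), c), ((a, c), b), ((b, c), a)):
            lca_pair = tree.lca_or_root(*pair)
            lca_all = tree.lca_or_root(pair[0], outsider)
            if lca_pair is not lca_all and tree.node_depth(lca_pair) > tree.node_depth(lca_all):
                out.add((pair, outsider))
    return out
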