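import numpy as np
import pytest

from mcta.taxonomy import TaxonNode, TaxonomyTree

# 15-node ladder with every rank, a norank insertion, a subspecies leaf,
# and two family branches so LCA/rank queries have non-trivial answers.
_LADDER_ROWS = [
    ("root", None, "root"),
    ("sk", "root", "superkingdom"),
    ("phy", "sk", "phylum"),
    ("nor", "phy", "norank"),
    ("cls", "nor", "class"),
    ("ord", "cls", "order"),
    ("fam", "ord", "family"),
    ("gen", "fam", "genus"),
    ("spA", "gen", "species"),
    ("spB", "gen", "species"),
    ("subA", "spA", "subspecies"),
    ("fam2", "ord", "family"),
    ("gen2", "fam2", "genus"),
    ("spC", "gen2", "species"),
    ("spD", "gen2", "species"),
]


@pytest.fixture(scope="session")
def ladder_tree() -> TaxonomyTree:
    nodes = {
        tid: TaxonNode(tid, tid.upper(), rank, parent)
        for tid, parent, rank in _LADDER_ROWS
    }
    return TaxonomyTree(nodes)


def make_random_tree(n: int, seed: int) -> TaxonomyTree:
    """Random rooted tree (norank internals) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    nodes = {"n0": TaxonNode("n0", "n0", "root", None)}
    for i in range(1, n):
        parent = f"n{rng.integers(0, i)}"
        nodes[f"n{i}"] = TaxonNode(f"n{i}", f"n{i}", "norank", parent)
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, taxa) -> str:
    """Independent oracle: deepest node common to every root-to-node path."""
    paths = [tree.lineage(t) for t in taxa]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    return max(common, key=lambda t: len(tree.lineage(t)))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
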