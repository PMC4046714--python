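"""Rank-labeled reference taxonomy with LCA and rank-ancestor queries.

The taxonomy is a rooted tree whose nodes carry one of eight named ranks
(root, superkingdom, phylum, class, order, family, genus, species,
subspecies) or ``norank``.  Cluster annotation assigns the lowest common
ancestor (LCA) of a set of taxa; evaluation asks for the ancestor of a
taxon at a fixed rank ("is this read annotated at or below its reference
level?").  Both queries live here.

The on-disk format is a 4-column TSV ``taxon_id  parent_id  rank  name``;
the root is encoded as its own parent (or with an empty parent field).
NCBI taxdump dialects are deliberately not parsed — convert externally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

#: Named ranks ordered from shallowest to deepest.  ``subspecies`` sorts
#: below ``species`` for the species-or-lower cluster-merge rule.
RANKS = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "subspecies",
)
NORANK = "norank"
RANK_DEPTH: Mapping[str, int] = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Malformed taxonomy input (duplicates, dangling parents, cycles)."""


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent_id: str | None  # None only for the root


class TaxonomyTree:
    """Validated rooted taxonomy supporting ancestry queries.

    Parameters
    ----------
    nodes:
        Mapping of taxon_id to :class:`TaxonNode`.  Exactly one node must
        have ``parent_id is None``; every other parent_id must resolve.
    """

    def __init__(self, nodes: Mapping[str, TaxonNode]):
        self.nodes: dict[str, TaxonNode] = dict(nodes)
        roots = [t for t, n in self.nodes.items() if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root_id: str = roots[0]
        self._depth: dict[str, int] = {}
        self._validate()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        for tid, node in self.nodes.items():
            if node.rank != NORANK and node.rank not in RANK_DEPTH:
                raise TaxonomyError(f"unknown rank {node.rank!r} for taxon {tid!r}")
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"taxon {tid!r} references missing parent {node.parent_id!r}"
                )
        # depth computation doubles as the cycle check
        for tid in self.nodes:
            self._depth_of(tid, _guard=set())
        # ranked depth must increase root-to-leaf (norank interleaves freely)
        for tid, node in self.nodes.items():
            if node.rank == NORANK or node.parent_id is None:
                continue
            anc_rank = self._nearest_ranked_ancestor_rank(node.parent_id)
            if anc_rank is not None and RANK_DEPTH[node.rank] <= RANK_DEPTH[anc_rank]:
                raise TaxonomyError(
                    f"rank order violated at {tid!r}: {node.rank} under {anc_rank}"
                )

    def _nearest_ranked_ancestor_rank(self, tid: str) -> str | None:
        cur: str | None = tid
        while cur is not None:
            node = self.nodes[cur]
            if node.rank != NORANK:
                return node.rank
            cur = node.parent_id
        return None

    def _depth_of(self, tid: str, _guard: set[str]) -> int:
        if tid in self._depth:
            return self._depth[tid]
        if tid in _guard:
            raise TaxonomyError(f"cycle detected at taxon {tid!r}")
        _guard.add(tid)
        parent = self.nodes[tid].parent_id
        d = 0 if parent is None else self._depth_of(parent, _guard) + 1
        self._depth[tid] = d
        return d

    # -- queries ------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon_id!r}") from None

    def rank(self, taxon_id: str) -> str:
        return self.node(taxon_id).rank

    def depth(self, taxon_id: str) -> int:
        self.node(taxon_id)
        return self._depth[taxon_id]

    def lineage(self, taxon_id: str) -> list[str]:
        """Root-to-node path of taxon_ids (inclusive at both ends)."""
        path = []
        cur: str | None = taxon_id
        while cur is not None:
            path.append(cur)
            cur = self.node(cur).parent_id
        path.reverse()
        return path

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        common: str | None = None
        common_path: list[str] = []
        for t in taxa:
            path = self.lineage(t)
            if common is None:
                common_path = path
            else:
                n = min(len(common_path), len(path))
                i = 0
                while i < n and common_path[i] == path[i]:
                    i += 1
                common_path = common_path[:i]
            common = common_path[-1]
        assert common is not None
        return common

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Unique ancestor-or-self of ``taxon_id`` at ``rank``, or None.

        ``rank`` must be one of the named ranks; norank nodes on the path
        are transparently skipped.
        """
        if rank not in RANK_DEPTH:
            raise ValueError(f"not a ranked label: {rank!r}")
        cur: str | None = taxon_id
        self.node(taxon_id)
        while cur is not None:
            node = self.nodes[cur]
            if node.rank == rank:
                return cur
            cur = node.parent_id
        return None

    def is_ancestor_or_equal(self, a: str, b: str) -> bool:
        """True iff ``a`` lies on the path from ``b`` to the root (inclusive)."""
        self.node(a)
        cur: str | None = b
        self.node(b)
        while cur is not None:
            if cur == a:
                return True
            cur = self.nodes[cur].parent_id
        return False


def load_taxonomy(source) -> TaxonomyTree:
    """Load a taxonomy from 4-column TSV (taxon_id, parent_id, rank, name).

    ``source`` may be a path or an open text stream.  The root row has an
    empty parent_id or one equal to its own taxon_id.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8", newline="") as fh:
            return load_taxonomy(fh)
    nodes: dict[str, TaxonNode] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise TaxonomyError(f"line {lineno}: expected 4 columns, got {len(fields)}")
        tid, parent, rank, name = (f.strip() for f in fields)
        if not tid:
            raise TaxonomyError(f"line {lineno}: empty taxon_id")
        if tid in nodes:
            raise TaxonomyError(f"line {lineno}: duplicate taxon_id {tid!r}")
        parent_id = None if (parent == "" or parent == tid) else parent
        nodes[tid] = TaxonNode(taxon_id=tid, name=name, rank=rank, parent_id=parent_id)
    return TaxonomyTree(nodes)


def dump_taxonomy(tree: TaxonomyTree, stream: io.TextIOBase) -> None:
    """Write a tree back to the 4-column TSV format (root as self-parent)."""
    stream.write("#taxon_id\tparent_id\trank\tname\n")
    for tid in sorted(tree.nodes):
        node = tree.nodes[tid]
        parent = node.parent_id if node.parent_id is not None else tid
        stream.write(f"{tid}\t{parent}\t{node.rank}\t{node.name}\n")


# Thin functional aliases mirroring the query surface; some callers prefer
# free functions over methods.
def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    return tree.lca(taxa)


def ancestor_at_rank(tree: TaxonomyTree, taxon: str, rank: str) -> str | None:
    return tree.ancestor_at_rank(taxon, rank)


def is_ancestor_or_equal(tree: TaxonomyTree, a: str, b: str) -> bool:
    return tree.is_ancestor_or_equal(a, b)
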