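"""Phase 3: cluster annotation by LCA of best-hit references, and merging.

Each contig in a cluster is matched against the reference genomes; the
cluster (and every read in it) is annotated to the lowest common
ancestor of the hit genomes' taxa.  Clusters annotated to the same
species (or lower) are then merged — they are evidence of one organism —
while clusters meeting only at genus or above are left apart, since they
may hold different species of one genus.

The built-in scorer counts a contig's distinct canonical seed k-mers
(k = 12) present in each reference genome, a cheap surrogate for an
ungapped alignment score; precomputed tabular hits (BLAST outfmt-6) can
be imported instead and follow the same best-hit-by-score rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmers import canonical_codes
from .seqio import SequenceRecord
from .taxonomy import RANK_DEPTH, TaxonomyTree

#: Sentinel annotation for clusters with no contig hits.
UNASSIGNED = "UNASSIGNED"

#: Ranks deep enough to trigger cluster merging ("same species or lower").
_MERGEABLE_RANKS = frozenset(r for r, d in RANK_DEPTH.items() if d >= RANK_DEPTH["species"])


class AnnotationDataError(ValueError):
    """Hit references a genome or taxon absent from the database/taxonomy."""


class ReferenceDB:
    """Reference genomes with taxon labels and a canonical seed-k-mer index.

    Internally each genome keeps a sorted array of its canonical seed
    k-mer codes, so scoring a contig is a vectorized membership test.
    """

    def __init__(
        self,
        genomes: Mapping[str, str],
        taxa: Mapping[str, str],
        tree: TaxonomyTree,
        seed_k: int = 12,
    ):
        self.seed_k = seed_k
        self.taxa: dict[str, str] = {}
        self._codes: dict[str, np.ndarray] = {}
        for gid in sorted(genomes):
            taxon = taxa[gid]
            if taxon not in tree:
                raise AnnotationDataError(f"genome {gid!r} has unknown taxon {taxon!r}")
            self.taxa[gid] = taxon
            self._codes[gid] = canonical_codes(genomes[gid], seed_k)

    def __len__(self) -> int:
        return len(self.taxa)

    def genome_ids(self) -> list[str]:
        return sorted(self.taxa)

    def seed_kmer_count(self, genome_id: str) -> int:
        return int(self._codes[genome_id].size)

    def score(self, contig_codes: np.ndarray, genome_id: str) -> int:
        """Number of the contig's distinct canonical seed k-mers present
        in the genome."""
        ref = self._codes[genome_id]
        if contig_codes.size == 0 or ref.size == 0:
            return 0
        idx = np.searchsorted(ref, contig_codes)
        idx[idx == ref.size] = ref.size - 1
        return int((ref[idx] == contig_codes).sum())


@dataclass
class ClusterAnnotationRecord:
    cluster_id: str
    taxon_id: str  # a taxon_id, or UNASSIGNED
    contig_hits: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_contigs_total: int = 0


def best_hit_genome(
    contig: SequenceRecord,
    db: ReferenceDB,
    min_hit_fraction: float = 0.05,
) -> tuple[str, int] | None:
    """Best-scoring reference for one contig, or None.

    The hit must cover at least ``min_hit_fraction`` of the contig's
    distinct seed k-mers: same-species relatives share most seeds, an
    order-level relative still clears 5%, while an unrelated genome's
    chance sharing stays below it.  Ties break to the smallest genome id.
    """
    codes = canonical_codes(contig.sequence, db.seed_k)
    if codes.size == 0 or len(db) == 0:
        return None
    best_gid: str | None = None
    best_score = -1
    for gid in db.genome_ids():
        s = db.score(codes, gid)
        if s > best_score:
            best_gid, best_score = gid, s
    if best_gid is None or best_score < min_hit_fraction * codes.size:
        return None
    return best_gid, best_score


def best_hits_from_table(
    rows: Iterable[tuple[str, str, float]]
) -> dict[str, tuple[str, float]]:
    """Per-query best subject by bitscore from imported tabular hits.

    Score ties break to the lexicographically smallest subject id.
    """
    best: dict[str, tuple[str, float]] = {}
    for query, subject, score in rows:
        cur = best.get(query)
        if cur is None or score > cur[1] or (score == cur[1] and subject < cur[0]):
            best[query] = (subject, score)
    return best


def annotate_cluster(
    cluster_id: str,
    contigs: Sequence[SequenceRecord],
    db: ReferenceDB,
    tree: TaxonomyTree,
    imported_hits: Mapping[str, tuple[str, float]] | None = None,
    min_hit_fraction: float = 0.05,
) -> ClusterAnnotationRecord:
    """Annotate one cluster to the LCA of its contigs' best-hit genomes.

    Only contigs are matched against the references — reads inherit the
    cluster annotation later.  A cluster with no contigs, or whose
    contigs all miss, is UNASSIGNED.
    """
    hits: dict[str, tuple[str, float]] = {}
    for contig in contigs:
        if imported_hits is not None:
            hit = imported_hits.get(contig.id)
            if hit is not None and hit[0] not in db.taxa:
                raise AnnotationDataError(f"hit genome {hit[0]!r} not in reference db")
        else:
            bh = best_hit_genome(contig, db, min_hit_fraction)
            hit = (bh[0], float(bh[1])) if bh is not None else None
        if hit is not None:
            hits[contig.id] = hit
    if not hits:
        taxon = UNASSIGNED
    else:
        taxon = tree.lca({db.taxa[gid] for gid, _ in hits.values()})
    return ClusterAnnotationRecord(
        cluster_id=cluster_id,
        taxon_id=taxon,
        contig_hits=hits,
        n_contigs_total=len(contigs),
    )


def merge_clusters_by_annotation(
    records: Sequence[ClusterAnnotationRecord],
    tree: TaxonomyTree,
) -> tuple[list[ClusterAnnotationRecord], dict[str, str]]:
    """Union clusters sharing a species-or-lower annotation.

    Clusters annotated at genus or higher never merge; neither do
    UNASSIGNED clusters.  Merged records pool their hits and recompute
    the LCA; the surviving cluster_id is the smallest of the group.
    Returns ``(merged_records, old_id -> merged_id)``.

    The operation is idempotent: pooled hits of same-taxon clusters have
    the same LCA, so a second pass changes nothing.
    """
    groups: dict[str, list[ClusterAnnotationRecord]] = {}
    singles: list[ClusterAnnotationRecord] = []
    for rec in records:
        if rec.taxon_id != UNASSIGNED and tree.rank(rec.taxon_id) in _MERGEABLE_RANKS:
            groups.setdefault(rec.taxon_id, []).append(rec)
        else:
            singles.append(rec)
    out: list[ClusterAnnotationRecord] = []
    id_map: dict[str, str] = {}
    for rec in singles:
        out.append(rec)
        id_map[rec.cluster_id] = rec.cluster_id
    for taxon, members in groups.items():
        if len(members) == 1:
            out.append(members[0])
            id_map[members[0].cluster_id] = members[0].cluster_id
            continue
        keep = min(m.cluster_id for m in members)
        pooled: dict[str, tuple[str, float]] = {}
        total = 0
        for m in members:
            pooled.update(m.contig_hits)
            total += m.n_contigs_total
            id_map[m.cluster_id] = keep
        # the LCA of pooled hits equals the LCA of the member LCAs, and all
        # members share annotation `taxon`, so recomputation is the identity
        out.append(
            ClusterAnnotationRecord(
                cluster_id=keep,
                taxon_id=taxon,
                contig_hits=pooled,
                n_contigs_total=total,
            )
        )
    out.sort(key=lambda r: r.cluster_id)
    return out, id_map


def propagate_to_reads(
    cluster_reads: Mapping[str, Iterable[str]],
    records: Sequence[ClusterAnnotationRecord],
) -> dict[str, str]:
    """Give every read its cluster's annotation (or UNASSIGNED).

    ``cluster_reads`` maps final cluster_id to its read ids and must
    cover each read exactly once.
    """
    by_id = {r.cluster_id: r for r in records}
    out: dict[str, str] = {}
    for cid, reads in cluster_reads.items():
        rec = by_id.get(cid)
        if rec is None:
            raise AnnotationDataError(f"no annotation record for cluster {cid!r}")
        for rid in reads:
            if rid in out:
                raise AnnotationDataError(f"read {rid!r} appears in multiple clusters")
            out[rid] = rec.taxon_id
    return out


def annotate_reads_per_contig(
    read_to_contig: Mapping[str, str],
    unassigned_reads: Iterable[str],
    contigs: Sequence[SequenceRecord],
    db: ReferenceDB,
    imported_hits: Mapping[str, tuple[str, float]] | None = None,
    min_hit_fraction: float = 0.05,
) -> dict[str, str]:
    """No-binning baseline: each read inherits its own contig's best hit.

    Reads on a hitless contig, and reads attached to no contig, are
    UNASSIGNED.  This is the per-contig annotation strategy the clustered
    pipeline is compared against.
    """
    contig_taxon: dict[str, str] = {}
    for contig in contigs:
        if imported_hits is not None:
            hit = imported_hits.get(contig.id)
        else:
            bh = best_hit_genome(contig, db, min_hit_fraction)
            hit = (bh[0], float(bh[1])) if bh is not None else None
        if hit is not None:
            contig_taxon[contig.id] = db.taxa[hit[0]]
    out: dict[str, str] = {}
    for rid, cid in read_to_contig.items():
        out[rid] = contig_taxon.get(cid, UNASSIGNED)
    for rid in unassigned_reads:
        out[rid] = UNASSIGNED
    return out
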