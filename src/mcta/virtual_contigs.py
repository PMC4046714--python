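"""Phase 1: group reads and contigs into virtual contigs.

Reads are first attached to assembled contigs by near-exact ungapped
placement (>= 95% matching positions); each used contig with its reads
forms an initial cluster and every unattached read is a singleton
cluster.  Clusters are then merged whenever they share a long (w = 36)
canonical w-mer: w-mers of that length are effectively unique to a
species, so a single shared one is strong evidence of common origin,
while w-mers occurring in unusually many clusters are discarded as
repeat-like evidence.  Each merged group is a *virtual contig* — its
members need not be contiguous on the genome — summarised by its distinct
canonical w-mer set, from which a coverage-invariant length estimate
follows.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .kmers import canonical_kmers, revcomp
from .seqio import SequenceRecord

__all__ = [
    "InitialCluster",
    "VirtualContig",
    "canonical_kmers",
    "assign_reads_to_contigs",
    "build_initial_clusters",
    "merge_by_shared_wmers",
    "estimate_vc_length",
]


@dataclass
class InitialCluster:
    cluster_id: str
    read_ids: set[str] = field(default_factory=set)
    contig_ids: set[str] = field(default_factory=set)


@dataclass
class VirtualContig:
    vc_id: str
    read_ids: set[str]
    contig_ids: set[str]
    wmers: set[str]
    estimated_length: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_reads_to_contigs(
    reads: Iterable[SequenceRecord],
    contigs: Iterable[SequenceRecord],
    min_identity: float = 0.95,
    min_contig_len: int = 500,
    seed_k: int = 16,
) -> tuple[dict[str, str], list[str]]:
    """Attach each read to the contig it matches best, if any.

    A read is assignable to a contig when some end-to-end ungapped
    placement (either strand, fully inside the contig) matches at a
    fraction >= ``min_identity`` of positions.  Candidate placements are
    found by exact ``seed_k``-mer seeding at a few read offsets and then
    verified over the full read.  Contigs shorter than ``min_contig_len``
    are ignored.  Among qualifying contigs the one with the most matching
    positions wins; ties go to the lexicographically smallest contig id.

    Returns ``(assignment, unassigned_read_ids)``.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    contig_seq: dict[str, str] = {}
    for c in contigs:
        if len(c.sequence) < min_contig_len:
            continue
        contig_seq[c.id] = c.sequence
        s = c.sequence
        for i in range(len(s) - seed_k + 1):
            km = s[i : i + seed_k]
            if "N" not in km:
                index[km].append((c.id, i))

    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for read in reads:
        seq = read.sequence
        m = len(seq)
        if m < seed_k or not contig_seq:
            unassigned.append(read.id)
            continue
        # a handful of disjoint seeds suffices: with <= floor((1-identity)*m)
        # mismatches at least one seed window is error-free
        offsets = list(range(0, m - seed_k + 1, seed_k))
        if offsets[-1] != m - seed_k:
            offsets.append(m - seed_k)
        best: dict[str, int] = {}
        for strand_seq in (seq, revcomp(seq)):
            seen: set[tuple[str, int]] = set()
            for off in offsets:
                for cid, pos in index.get(strand_seq[off : off + seed_k], ()):
                    start = pos - off
                    if start < 0 or start + m > len(contig_seq[cid]):
                        continue
                    key = (cid, start)
                    if key in seen:
                        continue
                    seen.add(key)
                    matches = m - _hamming(strand_seq, contig_seq[cid][start : start + m])
                    if matches > best.get(cid, -1):
                        best[cid] = matches
        qualifying = {c: s for c, s in best.items() if s / m >= min_identity}
        if qualifying:
            top = max(qualifying.values())
            assignment[read.id] = min(c for c, s in qualifying.items() if s == top)
        else:
            unassigned.append(read.id)
    return assignment, unassigned


def build_initial_clusters(
    assignment: Mapping[str, str],
    unassigned: Iterable[str],
    contig_ids: Iterable[str],
) -> list[InitialCluster]:
    """One cluster per contig (with its assigned reads) plus one singleton
    per unassigned read.  Together they partition the read set."""
    clusters: dict[str, InitialCluster] = {}
    for cid in contig_ids:
        clusters[f"c:{cid}"] = InitialCluster(cluster_id=f"c:{cid}", contig_ids={cid})
    for rid, cid in assignment.items():
        key = f"c:{cid}"
        if key not in clusters:
            raise ValueError(f"read {rid!r} assigned to unknown contig {cid!r}")
        clusters[key].read_ids.add(rid)
    out = [clusters[k] for k in sorted(clusters)]
    for rid in sorted(unassigned):
        out.append(InitialCluster(cluster_id=f"r:{rid}", read_ids={rid}))
    return out


def merge_by_shared_wmers(
    clusters: Sequence[InitialCluster],
    read_seqs: Mapping[str, str],
    contig_seqs: Mapping[str, str],
    w: int = 36,
    min_shared: int = 1,
    repeat_cap: int = 50,
) -> list[VirtualContig]:
    """Merge initial clusters sharing surviving canonical w-mers.

    Each cluster's w-mer set is the union over its members' canonical
    w-mers.  A w-mer occurring in more than ``repeat_cap`` distinct
    clusters is repeat-like and ignored as merge evidence (it still
    contributes to the summary).  Clusters sharing >= ``min_shared``
    surviving w-mers are merged transitively (disjoint-set semantics);
    the result is independent of input order.
    """
    n = len(clusters)
    order = sorted(range(n), key=lambda i: clusters[i].cluster_id)
    wmer_sets: list[set[str]] = [set() for _ in range(n)]
    for i, cl in enumerate(clusters):
        acc = wmer_sets[i]
        for cid in cl.contig_ids:
            acc |= canonical_kmers(contig_seqs[cid], w)
        for rid in cl.read_ids:
            acc |= canonical_kmers(read_seqs[rid], w)

    occurs: dict[str, list[int]] = defaultdict(list)
    for i in order:
        for km in wmer_sets[i]:
            lst = occurs[km]
            if len(lst) <= repeat_cap:  # cap + 1 entries suffice to disqualify
                lst.append(i)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if min_shared <= 1:
        for members in occurs.values():
            if 1 < len(members) <= repeat_cap:
                first = members[0]
                for other in members[1:]:
                    union(first, other)
    else:
        shared: dict[tuple[int, int], int] = defaultdict(int)
        for members in occurs.values():
            if 1 < len(members) <= repeat_cap:
                for a, b in combinations(sorted(members), 2):
                    shared[(a, b)] += 1
        for (a, b), count in shared.items():
            if count >= min_shared:
                union(a, b)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)

    # canonical vc ids: serial over groups sorted by smallest member cluster id
    keyed = sorted(groups.values(), key=lambda g: min(clusters[i].cluster_id for i in g))
    out: list[VirtualContig] = []
    for serial, members in enumerate(keyed):
        read_ids: set[str] = set()
        contig_ids: set[str] = set()
        wmers: set[str] = set()
        for i in members:
            read_ids |= clusters[i].read_ids
            contig_ids |= clusters[i].contig_ids
            wmers |= wmer_sets[i]
        vc = VirtualContig(
            vc_id=f"vc{serial:05d}",
            read_ids=read_ids,
            contig_ids=contig_ids,
            wmers=wmers,
            estimated_length=0,
        )
        vc.estimated_length = estimate_vc_length(vc, w)
        out.append(vc)
    return out


def estimate_vc_length(vc: VirtualContig, w: int = 36) -> int:
    """Length estimate from the distinct-w-mer count.

    A repeat-free sequence of length L has L - w + 1 distinct w-mers, so
    ``|wmers| + w - 1`` recovers L exactly in that case and is invariant
    to read coverage depth (duplicates collapse in the set).
    """
    if not vc.wmers:
        return 0
    return len(vc.wmers) + w - 1
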