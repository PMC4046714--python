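import numpy as np
import pytest

from mcta.kmers import canonical_kmers, revcomp
from mcta.seqio import SequenceRecord
from mcta.simulate import CommunityConfig, generate_community_data, random_genome
from mcta.virtual_contigs import (
    InitialCluster,
    VirtualContig,
    assign_reads_to_contigs,
    build_initial_clusters,
    estimate_vc_length,
    merge_by_shared_wmers,
)


def brute_canonical(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            out.add(min(km, revcomp(km)))
    return out


class TestCanonicalKmers:
    def test_palindromic_canonical(self):
        assert canonical_kmers("ACGT", 4) == {"ACGT"}

    def test_homopolymer(self):
        assert canonical_kmers("AAAAA", 4) == {"AAAA"}

    def test_shorter_than_k_empty(self):
        assert canonical_kmers("ACG", 4) == set()

    def test_n_windows_skipped(self):
        # windows CN and NG are dropped; GT canonicalizes to AC
        assert canonical_kmers("ACNGT", 2) == {"AC"}

    def test_matches_brute_force_on_random_sequence(self, rng):
        seq = random_genome(1000, rng)
        for k in (4, 16, 36):
            assert canonical_kmers(seq, k) == brute_canonical(seq, k)

    def test_strand_invariance(self, rng):
        seq = random_genome(300, rng)
        assert canonical_kmers(seq, 21) == canonical_kmers(revcomp(seq), 21)


def _mismatch(seq: str, positions, base_map={"A": "C", "C": "G", "G": "T", "T": "A"}):
    s = list(seq)
    for p in positions:
        s[p] = base_map[s[p]]
    return "".join(s)


@pytest.fixture(scope="module")
def contig():
    return SequenceRecord("ctg1", random_genome(1000, np.random.default_rng(42)))


class TestAssignReadsToContigs:

    def test_exact_substring_assigned(self, contig):
        read = SequenceRecord("r1", contig.sequence[100:175])
        assignment, unassigned = assign_reads_to_contigs([read], [contig])
        assert assignment == {"r1": "ctg1"} and unassigned == []

    def test_reverse_strand_assigned(self, contig):
        read = SequenceRecord("r1", revcomp(contig.sequence[300:375]))
        assignment, _ = assign_reads_to_contigs([read], [contig])
        assert assignment == {"r1": "ctg1"}

    def test_identity_threshold_arithmetic(self, contig):
        """3 mismatches in 75 bp (96%) assign; 4 (94.7%) do not."""
        base = contig.sequence[200:275]
        r3 = SequenceRecord("r3", _mismatch(base, [5, 30, 70]))
        r4 = SequenceRecord("r4", _mismatch(base, [5, 30, 55, 70]))
        assignment, unassigned = assign_reads_to_contigs([r3, r4], [contig])
        assert assignment == {"r3": "ctg1"}
        assert unassigned == ["r4"]

    def test_short_contigs_excluded(self):
        contig = SequenceRecord("short", "ACGT" * 100)  # 400 bp < 500
        read = SequenceRecord("r", contig.sequence[:75])
        assignment, unassigned = assign_reads_to_contigs([read], [contig])
        assert assignment == {} and unassigned == ["r"]

    def test_best_contig_wins_ties_lexicographic(self, contig):
        exact = SequenceRecord("a_copy", contig.sequence[:600])
        worse = SequenceRecord("z_copy", _mismatch(contig.sequence[:600], [50]))
        read = SequenceRecord("r", contig.sequence[10:85])
        assignment, _ = assign_reads_to_contigs([read], [exact, worse])
        assert assignment["r"] == "a_copy"
        # identical contigs: lexicographically smaller id wins
        twin = SequenceRecord("b_copy", exact.sequence)
        assignment, _ = assign_reads_to_contigs([read], [twin, exact])
        assert assignment["r"] == "a_copy"

    def test_error_free_full_tiling_assigns_nearly_all(self, rng):
        cfg = CommunityConfig(n_targets=1, genome_length=20_000, error_rate=0.0,
                              contig_fraction=1.0, coverages=[5.0], seed=8,
                              reference_levels=["species"])
        com = generate_community_data(cfg)
        reads = [m for p in com.read_pairs for m in (p.mate1, p.mate2)]
        assignment, unassigned = assign_reads_to_contigs(reads, com.contigs)
        # reads spanning contig junctions cannot place end-to-end; >=99% of
        # reads lie inside one contig and must all be recovered
        assert len(assignment) / len(reads) >= 0.90
        inside = 0
        truth = {t.read_id: t for t in com.truth}
        spans = {c.id: (int(c.description.split(":")[1]), len(c.sequence)) for c in com.contigs}
        for r in reads:
            t = truth[r.id]
            if any(s <= t.start and t.start + 75 <= s + L for s, L in spans.values()):
                inside += 1
                assert r.id in assignment
        assert inside / len(reads) >= 0.9


class TestBuildInitialClusters:
    def test_no_assignment_all_singletons(self):
        clusters = build_initial_clusters({}, ["r1", "r2"], [])
        assert [c.cluster_id for c in clusters] == ["r:r1", "r:r2"]
        assert all(len(c.read_ids) == 1 and not c.contig_ids for c in clusters)

    def test_all_reads_on_one_contig(self):
        clusters = build_initial_clusters({"r1": "c1", "r2": "c1"}, [], ["c1"])
        assert len(clusters) == 1
        assert clusters[0].read_ids == {"r1", "r2"}

    def test_cluster_count_is_contigs_plus_unassigned(self):
        clusters = build_initial_clusters(
            {"r1": "c1", "r2": "c2"}, ["r3", "r4", "r5"], ["c1", "c2"]
        )
        assert len(clusters) == 2 + 3
        all_reads = [r for c in clusters for r in c.read_ids]
        assert sorted(all_reads) == ["r1", "r2", "r3", "r4", "r5"]  # partition


def _cluster(cid, reads=(), contigs=()):
    return InitialCluster(cid, set(reads), set(contigs))


class TestMergeBySharedWmers:
    W = 36

    def _seqs(self, rng, n=4, length=200):
        return [random_genome(length, rng) for _ in range(n)]

    def test_no_shared_wmers_never_merged(self, rng):
        a, b = self._seqs(rng, 2)
        clusters = [_cluster("c:a", contigs=["a"]), _cluster("c:b", contigs=["b"])]
        vcs = merge_by_shared_wmers(clusters, {}, {"a": a, "b": b})
        assert len(vcs) == 2

    def test_transitive_merge(self, rng):
        g = random_genome(600, rng)
        # A,B overlap on [250,320); B,C on [450,520); A,C share nothing
        a, b, c = g[:320], g[250:520], g[450:]
        clusters = [_cluster("c:a", contigs=["a"]), _cluster("c:b", contigs=["b"]),
                    _cluster("c:c", contigs=["c"])]
        vcs = merge_by_shared_wmers(clusters, {}, {"a": a, "b": b, "c": c})
        assert len(vcs) == 1
        assert vcs[0].contig_ids == {"a", "b", "c"}

    def test_repeat_cap_discards_promiscuous_wmers(self, rng):
        shared = random_genome(40, rng)
        clusters = [_cluster(f"r:{i}", reads=[f"read{i}"]) for i in range(5)]
        read_seqs = {f"read{i}": shared for i in range(5)}
        # every w-mer occurs in all 5 clusters; cap 3 disqualifies them all
        vcs = merge_by_shared_wmers(clusters, read_seqs, {}, repeat_cap=3)
        assert len(vcs) == 5
        vcs = merge_by_shared_wmers(clusters, read_seqs, {}, repeat_cap=10)
        assert len(vcs) == 1

    def test_min_shared_monotone_fragmentation(self, rng):
        g = random_genome(1200, rng)
        seqs = {f"s{i}": g[i * 150 : i * 150 + 300] for i in range(6)}
        clusters = [_cluster(f"c:s{i}", contigs=[f"s{i}"]) for i in range(6)]
        counts = []
        for min_shared in (1, 50, 200, 1000):
            vcs = merge_by_shared_wmers(clusters, {}, seqs, min_shared=min_shared)
            counts.append(len(vcs))
        assert counts == sorted(counts)

    def test_order_independence(self, rng):
        g1, g2 = self._seqs(rng, 2, 800)
        clusters = [
            _cluster("c:a", contigs=["a"]), _cluster("c:b", contigs=["b"]),
            _cluster("r:x", reads=["x"]), _cluster("r:y", reads=["y"]),
        ]
        seqs = {"a": g1[:500], "b": g1[300:], "x": g2[:75], "y": g1[450:525]}
        read_seqs = {"x": seqs["x"], "y": seqs["y"]}
        contig_seqs = {"a": seqs["a"], "b": seqs["b"]}

        def partition(cl):
            vcs = merge_by_shared_wmers(cl, read_seqs, contig_seqs)
            return {frozenset(v.read_ids | v.contig_ids) for v in vcs}

        assert partition(clusters) == partition(clusters[::-1])

    def test_read_partition_preserved(self, rng):
        cfg = CommunityConfig(n_targets=2, genome_length=10_000, coverages=[3, 3],
                              contig_fraction=0.4, seed=5)
        com = generate_community_data(cfg)
        reads = [m for p in com.read_pairs for m in (p.mate1, p.mate2)]
        read_seqs = {r.id: r.sequence for r in reads}
        contig_seqs = {c.id: c.sequence for c in com.contigs}
        assignment, unassigned = assign_reads_to_contigs(reads, com.contigs)
        clusters = build_initial_clusters(assignment, unassigned, sorted(contig_seqs))
        vcs = merge_by_shared_wmers(clusters, read_seqs, contig_seqs)
        placed = [r for v in vcs for r in v.read_ids]
        assert sorted(placed) == sorted(read_seqs)  # no read lost or duplicated


class TestEstimateVcLength:
    def _vc(self, wmers):
        return VirtualContig("vc", set(), set(), wmers, 0)

    def test_exact_on_repeat_free_contig(self, rng):
        seq = random_genome(1000, rng)
        wmers = canonical_kmers(seq, 36)
        assert len(wmers) == 965  # repeat-free at w=36
        assert estimate_vc_length(self._vc(wmers)) == 1000

    def test_coverage_invariant(self, rng):
        seq = random_genome(2000, rng)
        base = canonical_kmers(seq, 36)
        # overlapping 75-mers tiling the sequence at ~20x only duplicate w-mers
        tiled = set()
        for start in range(0, 2000 - 75, 4):
            tiled |= canonical_kmers(seq[start : start + 75], 36)
        assert tiled <= base
        assert estimate_vc_length(self._vc(base)) == estimate_vc_length(
            self._vc(tiled | base)
        )

    def test_two_disjoint_fragments_bounded_loss(self, rng):
        g = random_genome(5000, rng)
        frags = [g[:600], g[2000:2700]]
        wmers = set().union(*(canonical_kmers(f, 36) for f in frags))
        est = estimate_vc_length(self._vc(wmers))
        assert 1230 <= est <= 1300  # each fragment loses at most w-1

    def test_empty_summary_is_zero(self):
        assert estimate_vc_length(self._vc(set())) == 0
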