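from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mcta.clustering import (
    CompositionProfile,
    assign_short_vcs,
    build_cluster_models,
    composition_profile,
    kmeans_spearman,
    spearman_distance,
    split_by_length,
)
from mcta.kmers import canonical_index, canonical_kmers, profile_dimension, revcomp
from mcta.simulate import random_genome
from mcta.virtual_contigs import VirtualContig


def _vc(wmers, vc_id="vc", length=None):
    vc = VirtualContig(vc_id, set(), set(), set(wmers), 0)
    vc.estimated_length = length if length is not None else len(vc.wmers) + 35
    return vc


def _profile_from_values(values):
    v = np.asarray(values, dtype=float)
    return CompositionProfile(q=4, values=v / v.sum())


def brute_profile(wmers, q):
    """Independent oracle: per-w-mer window counting with string canonicalization."""
    counts = Counter()
    for wm in wmers:
        for i in range(len(wm) - q + 1):
            km = wm[i : i + q]
            counts[min(km, revcomp(km))] += 1
    _, canon = canonical_index(q)
    vec = np.array([counts.get(k, 0) for k in canon], dtype=float)
    return vec / vec.sum()


class TestCompositionProfile:
    def test_dimensions(self):
        assert profile_dimension(4) == 136
        assert profile_dimension(5) == 512

    def test_homopolymer_wmer_concentrates_mass(self):
        prof = composition_profile(_vc({"A" * 36}), 4)
        _, canon = canonical_index(4)
        assert prof.values[canon.index("AAAA")] == 1.0

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            composition_profile(_vc(set()), 4)

    def test_coverage_doubling_leaves_profile_identical(self, rng):
        seq = random_genome(3000, rng)
        once = set()
        for start in range(0, 3000 - 74, 15):  # ~5x tiling of the region
            once |= canonical_kmers(seq[start : start + 75], 36)
        twice = set(once)
        for start in range(7, 2800, 15):  # a second staggered pass inside it
            twice |= canonical_kmers(seq[start : start + 75], 36)
        assert twice == once  # duplicate coverage collapses in the distinct set
        p1 = composition_profile(_vc(once), 5)
        p2 = composition_profile(_vc(twice), 5)
        assert np.array_equal(p1.values, p2.values)

    @pytest.mark.parametrize("q", [4, 5])
    def test_matches_brute_force_on_random_vcs(self, q, rng):
        for _ in range(50):
            seq = random_genome(int(rng.integers(100, 400)), rng)
            wmers = canonical_kmers(seq, 36)
            got = composition_profile(_vc(wmers), q).values
            np.testing.assert_allclose(got, brute_profile(wmers, q), atol=1e-12)


def oracle_spearman_distance(x, y):
    """Rank-then-correlate with hand-computed average ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return np.array(ranks)

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return 1 - float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))


class TestSpearmanDistance:
    def test_identity_is_zero(self, rng):
        p = _profile_from_values(rng.random(136) + 0.01)
        assert spearman_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_rank_reversal_is_two(self):
        up = _profile_from_values(np.arange(1, 137, dtype=float))
        down = _profile_from_values(np.arange(136, 0, -1, dtype=float))
        assert spearman_distance(up, down) == pytest.approx(2.0, abs=1e-12)

    def test_constant_profile_defaults_to_one(self):
        flat = _profile_from_values(np.ones(136))
        other = _profile_from_values(np.arange(1, 137, dtype=float))
        assert spearman_distance(flat, other) == pytest.approx(1.0)

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.random(136)
            b = rng.random(136)
            # inject ties to exercise average ranks
            a[rng.integers(0, 136, 10)] = a[0]
            pa, pb = _profile_from_values(a), _profile_from_values(b)
            assert spearman_distance(pa, pb) == pytest.approx(
                oracle_spearman_distance(pa.values, pb.values), abs=1e-12
            )

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            pa = _profile_from_values(rng.random(136) + 1e-3)
            pb = _profile_from_values(rng.random(136) + 1e-3)
            d1, d2 = spearman_distance(pa, pb), spearman_distance(pb, pa)
            assert d1 == d2
            assert 0.0 <= d1 <= 2.0


def planted_profiles(rng, q=5, per_group=20, noise=0.02):
    """Two groups around rank-distinct prototypes, lightly perturbed."""
    dim = profile_dimension(q)
    protos = [rng.permutation(np.arange(1, dim + 1, dtype=float)) for _ in range(2)]
    profiles, labels = [], []
    for g, proto in enumerate(protos):
        base = proto / proto.sum()
        for _ in range(per_group):
            v = base * (1 + noise * rng.standard_normal(dim))
            v = np.clip(v, 1e-9, None)
            profiles.append(CompositionProfile(q, v / v.sum()))
            labels.append(g)
    return profiles, np.array(labels)


class TestKmeansSpearman:
    def test_k1_single_cluster(self, rng):
        profiles, _ = planted_profiles(rng, per_group=5)
        labels = kmeans_spearman(profiles, 1)
        assert set(labels) == {0}

    def test_k_exceeding_n_rejected(self, rng):
        profiles, _ = planted_profiles(rng, per_group=2)
        with pytest.raises(ValueError):
            kmeans_spearman(profiles, 5)

    def test_planted_partition_recovered(self, rng):
        profiles, truth = planted_profiles(rng)
        labels = kmeans_spearman(profiles, 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_objective_non_increasing(self, rng):
        profiles, _ = planted_profiles(rng, per_group=15, noise=0.3)
        history: list[float] = []
        kmeans_spearman(profiles, 3, seed=1, objective_history=history)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_partition_invariant_to_input_order(self, rng):
        profiles, _ = planted_profiles(rng, per_group=10, noise=0.1)
        perm = rng.permutation(len(profiles))
        labels_a = kmeans_spearman(profiles, 2, seed=3)
        labels_b = kmeans_spearman([profiles[i] for i in perm], 2, seed=3)
        part_a = {frozenset(np.flatnonzero(labels_a == l)) for l in set(labels_a)}
        part_b = {
            frozenset(perm[i] for i in np.flatnonzero(labels_b == l))
            for l in set(labels_b)
        }
        assert part_a == part_b


class TestSplitByLength:
    def test_boundary_at_threshold(self):
        exactly = _vc({"A" * 36}, "a", length=10_000)
        below = _vc({"A" * 36}, "b", length=9_999)
        long_vcs, short_vcs = split_by_length([exactly, below])
        assert [v.vc_id for v in long_vcs] == ["a"]
        assert [v.vc_id for v in short_vcs] == ["b"]

    def test_empty_input(self):
        assert split_by_length([]) == ([], [])


class TestAssignShortVcs:
    def _genome_vcs(self, rng, n_genomes=2, n_long=3, n_short=8):
        genomes = [random_genome(30_000, rng) for _ in range(n_genomes)]
        long_vcs, short_vcs, short_truth = [], [], []
        for g, genome in enumerate(genomes):
            for i in range(n_long):
                frag = genome[i * 10_000 : (i + 1) * 10_000 + 36]
                long_vcs.append(_vc(canonical_kmers(frag, 36), f"g{g}L{i}"))
            for i in range(n_short):
                start = int(rng.integers(0, 28_000))
                frag = genome[start : start + 2_000]
                short_vcs.append(_vc(canonical_kmers(frag, 36), f"g{g}S{i}"))
                short_truth.append(g)
        return long_vcs, short_vcs, short_truth

    def test_single_model_takes_everything(self, rng):
        long_vcs, short_vcs, _ = self._genome_vcs(rng, n_genomes=1)
        models = build_cluster_models(long_vcs, np.zeros(len(long_vcs), dtype=int))
        mapping = assign_short_vcs(short_vcs, models)
        assert set(mapping.values()) == {models[0].cluster_id}

    def test_member_content_maps_to_own_cluster(self, rng):
        long_vcs, _, _ = self._genome_vcs(rng, n_genomes=1, n_long=2)
        models = build_cluster_models(long_vcs, np.arange(2))
        shadow = _vc(set(long_vcs[1].wmers), "shadow")
        mapping = assign_short_vcs([shadow], models)
        assert mapping["shadow"] == models[1].cluster_id

    def test_planted_short_fragments_follow_source_genome(self, rng):
        long_vcs, short_vcs, short_truth = self._genome_vcs(rng)
        labels = np.array([0] * 3 + [1] * 3)
        models = build_cluster_models(long_vcs, labels)
        mapping = assign_short_vcs(short_vcs, models)
        correct = sum(
            mapping[v.vc_id] == models[g].cluster_id
            for v, g in zip(short_vcs, short_truth)
        )
        assert correct / len(short_vcs) >= 0.95

    def test_no_models_rejected(self):
        with pytest.raises(ValueError):
            assign_short_vcs([], [])
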