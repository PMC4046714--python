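"""Evaluation of binning and annotation against simulated ground truth.

Annotation outcomes per read (with true genome G at reference level L,
annotated taxon T):

* **Accurate** — T is on G's lineage at or below the rank-L ancestor
  (annotating *deeper* than L but still on-lineage is more informative
  than L, so it counts as Accurate);
* **Higher** — T is a strict ancestor of the rank-L ancestor (correct,
  but less specific than the reference level allows);
* **Incorrect** — G does not belong to taxon T (off-lineage);
* **Unassigned** — no annotation.

Binning quality uses the read-cluster count matrix R (rows clusters,
columns genomes): precision is the cluster-majority fraction over
assigned reads, sum_i max_j R_ij / sum_ij R_ij; sensitivity is the
genome-majority fraction over *all* reads, sum_j max_i R_ij / total.  A
species S is *discovered* by cluster C when strictly more than half of
S's reads are in C and strictly more than half of C's reads are from S.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from .annotation import UNASSIGNED
from .taxonomy import TaxonomyTree


class AnnotationOutcome(str, Enum):
    ACCURATE = "Accurate"
    HIGHER = "Higher"
    INCORRECT = "Incorrect"
    UNASSIGNED = "Unassigned"


@dataclass
class ReadClusterMatrix:
    cluster_ids: list[str]
    genome_ids: list[str]
    R: np.ndarray  # counts, shape (len(cluster_ids), len(genome_ids))
    unassigned_per_genome: np.ndarray  # shape (len(genome_ids),)
    total_reads: int


@dataclass
class EvaluationReport:
    """Outcome fractions per reference level plus binning metrics."""

    outcome_fractions: dict[str, dict[str, float]]  # level -> outcome name -> fraction
    outcome_counts: dict[str, Counter] = field(default_factory=dict)
    precision: float | None = None
    sensitivity: float | None = None
    discovered: dict[str, bool] = field(default_factory=dict)


def classify_read(
    genome_taxon: str,
    reference_level: str,
    annotated_taxon: str | None,
    tree: TaxonomyTree,
) -> AnnotationOutcome:
    """Classify one read's annotation outcome; see the module docstring."""
    if annotated_taxon is None or annotated_taxon == UNASSIGNED:
        return AnnotationOutcome.UNASSIGNED
    if annotated_taxon not in tree:
        raise KeyError(f"unknown annotated taxon {annotated_taxon!r}")
    anchor = tree.ancestor_at_rank(genome_taxon, reference_level)
    if anchor is None:
        raise ValueError(
            f"taxon {genome_taxon!r} has no ancestor at rank {reference_level!r}"
        )
    T = annotated_taxon
    if T == anchor or (
        tree.is_ancestor_or_equal(anchor, T) and tree.is_ancestor_or_equal(T, genome_taxon)
    ):
        return AnnotationOutcome.ACCURATE
    if tree.is_ancestor_or_equal(T, anchor) and T != anchor:
        return AnnotationOutcome.HIGHER
    return AnnotationOutcome.INCORRECT


def build_matrix(
    read_to_cluster: Mapping[str, str | None],
    truth: Mapping[str, str],
) -> ReadClusterMatrix:
    """Tally reads into the cluster-by-genome count matrix.

    ``read_to_cluster`` maps every read to a cluster id or None
    (unclustered); ``truth`` maps every read to its source genome.  A
    read missing from ``truth`` is a data error.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    unassigned: Counter = Counter()
    genomes: set[str] = set()
    clusters: set[str] = set()
    total = 0
    for rid, cid in read_to_cluster.items():
        if rid not in truth:
            raise KeyError(f"read {rid!r} has no ground truth")
        g = truth[rid]
        genomes.add(g)
        total += 1
        if cid is None:
            unassigned[g] += 1
        else:
            clusters.add(cid)
            counts[(cid, g)] += 1
    cluster_ids = sorted(clusters)
    genome_ids = sorted(genomes)
    R = np.zeros((len(cluster_ids), len(genome_ids)), dtype=np.int64)
    ci = {c: i for i, c in enumerate(cluster_ids)}
    gi = {g: j for j, g in enumerate(genome_ids)}
    for (c, g), n in counts.items():
        R[ci[c], gi[g]] = n
    un = np.array([unassigned.get(g, 0) for g in genome_ids], dtype=np.int64)
    return ReadClusterMatrix(cluster_ids, genome_ids, R, un, total)


def binning_precision(m: ReadClusterMatrix) -> float | None:
    """Cluster-majority purity over assigned reads; None if nothing assigned."""
    assigned = int(m.R.sum())
    if assigned == 0:
        return None
    return float(m.R.max(axis=1).sum() / assigned)


def binning_sensitivity(m: ReadClusterMatrix) -> float:
    """Genome-majority recovery over all reads (unassigned included)."""
    if m.total_reads == 0:
        raise ValueError("sensitivity undefined with zero reads")
    if m.R.size == 0:
        return 0.0
    return float(m.R.max(axis=0).sum() / m.total_reads)


def discovered_species(
    read_to_cluster: Mapping[str, str | None],
    truth_species: Mapping[str, str],
) -> dict[str, bool]:
    """Which species have a cluster holding >50% of their reads that is
    itself >50% composed of them (both strict)."""
    species_total: Counter = Counter()
    cluster_total: Counter = Counter()
    joint: dict[tuple[str, str], int] = defaultdict(int)
    for rid, cid in read_to_cluster.items():
        s = truth_species[rid]
        species_total[s] += 1
        if cid is not None:
            cluster_total[cid] += 1
            joint[(cid, s)] += 1
    out: dict[str, bool] = {}
    for s, n_s in species_total.items():
        found = False
        for (cid, sp), n in joint.items():
            if sp != s:
                continue
            if 2 * n > n_s and 2 * n > cluster_total[cid]:
                found = True
                break
        out[s] = found
    return out


def evaluate(
    read_annotations: Mapping[str, str],
    read_to_cluster: Mapping[str, str | None],
    truth_genome: Mapping[str, str],
    genome_taxon: Mapping[str, str],
    genome_reference_level: Mapping[str, str],
    tree: TaxonomyTree,
) -> EvaluationReport:
    """Full scorecard: per-level outcome fractions, binning metrics, discovery."""
    counts: dict[str, Counter] = defaultdict(Counter)
    for rid, taxon in read_annotations.items():
        g = truth_genome[rid]
        level = genome_reference_level[g]
        outcome = classify_read(genome_taxon[g], level, taxon, tree)
        counts[level][outcome.value] += 1
    fractions: dict[str, dict[str, float]] = {}
    for level, ctr in counts.items():
        total = sum(ctr.values())
        fractions[level] = {
            o.value: ctr.get(o.value, 0) / total for o in AnnotationOutcome
        }
    matrix = build_matrix(read_to_cluster, truth_genome)
    return EvaluationReport(
        outcome_fractions=fractions,
        outcome_counts=dict(counts),
        precision=binning_precision(matrix),
        sensitivity=binning_sensitivity(matrix),
        discovered=discovered_species(
            read_to_cluster, {r: truth_genome[r] for r in read_to_cluster}
        ),
    )
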