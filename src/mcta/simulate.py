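"""Synthetic community generator: taxonomy, genomes, reads, surrogate contigs.

Emulates the benchmark protocol for annotating *unknown* species: each
target genome is held out of the reference database, and the database
retains only relatives at a prescribed taxonomic distance (its
*reference level*).  A target with reference level ``species`` has
same-species relatives in the database; one with level ``order`` has
relatives in the same order but none in its family, genus or species.

Reads follow the standard short-read protocol: length-75 paired-end
reads with 1% substitution error and insert sizes of 250 +/- 50 bp
(Normal, truncated), sampled at a per-target coverage.  Contigs are
emitted as error-free non-overlapping substrings (>= 500 bp) covering a
configured fraction of each genome, standing in for an assembler.

Genome sequences are drawn from a per-genome random first-order Markov
chain (Dirichlet-distributed transition rows), giving each genome a
distinct oligonucleotide signature the way real genomes differ in GC and
codon usage; i.i.d. uniform sequences would render composition-based
clustering meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kmers import encode_bases, revcomp
from .seqio import ReadPairRecord, SequenceRecord, TruthRecord
from .taxonomy import TaxonNode, TaxonomyTree

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Reference levels the simulator knows how to construct.
REFERENCE_LEVELS = ("species", "genus", "family", "order")

#: Per-rank substitution divergence between a target and a relative whose
#: deepest shared ancestor has that rank.  Monotone in rank height so that
#: order-level relatives are far harder to hit with long exact matches
#: than same-species ones.
DEFAULT_DIVERGENCE: Mapping[str, float] = {
    "species": 0.02,
    "genus": 0.06,
    "family": 0.12,
    "order": 0.20,
}


class ConfigError(ValueError):
    """Inconsistent community configuration."""


@dataclass
class CommunityConfig:
    """Study conditions for one synthetic community.

    Defaults encode the benchmark protocol: 75 bp paired-end reads, 1%
    substitution error, Normal(250, 50) insert size, 15x coverage.
    """

    n_targets: int = 6
    genome_length: int = 100_000
    divergence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    reference_levels: Sequence[str] | None = None  # default: half species, half order
    coverages: Sequence[float] | None = None  # default: 15x each
    n_refs_per_target: int = 2
    read_length: int = 75
    error_rate: float = 0.01
    insert_mean: float = 250.0
    insert_sd: float = 50.0
    contig_fraction: float = 0.6
    seed: int = 0

    def resolved_levels(self) -> list[str]:
        if self.reference_levels is not None:
            return list(self.reference_levels)
        half = self.n_targets // 2
        return ["species"] * (self.n_targets - half) + ["order"] * half

    def resolved_coverages(self) -> list[float]:
        if self.coverages is not None:
            return [float(c) for c in self.coverages]
        return [15.0] * self.n_targets

    def validate(self) -> None:
        if self.n_targets < 1:
            raise ConfigError("n_targets must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.insert_mean < 2 * self.read_length:
            raise ConfigError("insert_mean must be >= 2 * read_length")
        if not 0.0 <= self.contig_fraction <= 1.0:
            raise ConfigError("contig_fraction must be in [0, 1]")
        if self.n_refs_per_target < 1:
            raise ConfigError("n_refs_per_target must be >= 1")
        d = self.divergence
        missing = [r for r in REFERENCE_LEVELS if r not in d]
        if missing:
            raise ConfigError(f"divergence map missing ranks: {missing}")
        if not (0 < d["species"] < d["genus"] < d["family"] < d["order"] < 1):
            raise ConfigError("divergence must strictly increase species<genus<family<order")
        levels = self.resolved_levels()
        if len(levels) != self.n_targets:
            raise ConfigError("reference_levels length must equal n_targets")
        for lv in levels:
            if lv not in REFERENCE_LEVELS:
                raise ConfigError(f"unsupported reference level {lv!r}")
        covs = self.resolved_coverages()
        if len(covs) != self.n_targets:
            raise ConfigError("coverages length must equal n_targets")
        if any(c < 0 for c in covs):
            raise ConfigError("coverage must be >= 0")


@dataclass
class Genome:
    genome_id: str
    sequence: str
    taxon_id: str


@dataclass
class CommunityTruth:
    """A generated community plus everything needed to score results."""

    taxonomy: TaxonomyTree
    targets: dict[str, Genome]
    references: dict[str, Genome]
    reference_level: dict[str, str]  # target genome_id -> rank
    coverage: dict[str, float]  # target genome_id -> coverage
    read_pairs: list[ReadPairRecord] = field(default_factory=list)
    truth: list[TruthRecord] = field(default_factory=list)
    contigs: list[SequenceRecord] = field(default_factory=list)


# ---------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def mutate_sequence(seq: str, subst_rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``subst_rate``.

    A substituted base is drawn uniformly from the three *other* bases, so
    rate 1 changes every position.  N positions are left untouched.
    """
    if not 0.0 <= subst_rate <= 1.0:
        raise ConfigError("subst_rate must be in [0, 1]")
    b = encode_bases(seq)
    mask = (rng.random(b.size) < subst_rate) & (b < 4)
    n_mut = int(mask.sum())
    if n_mut:
        b = b.copy()
        b[mask] = (b[mask] + rng.integers(1, 4, size=n_mut)) % 4
    has_n = (b >= 4).any()
    if not has_n:
        return _decode(b)
    out = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    valid = b < 4
    out[valid] = _DECODE[b[valid]]
    return out.tobytes().decode("ascii")


def random_genome(length: int, rng: np.random.Generator, concentration: float = 6.0) -> str:
    """Genome from a random first-order Markov chain.

    Transition rows are Dirichlet(``concentration``) draws, so each genome
    acquires its own dinucleotide bias and hence a distinctive q-mer
    spectrum while remaining sequence-random.
    """
    trans = rng.dirichlet(np.full(4, concentration), size=4)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(rng.integers(4))
    for i in range(length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        if state > 3:  # numerical edge when u ~ 1.0
            state = 3
        out[i] = state
    return _decode(out)


# ---------------------------------------------------------------------
# community construction
# ---------------------------------------------------------------------

_CHAIN_BELOW = {"species": (), "genus": ("species",), "family": ("genus", "species"),
                "order": ("family", "genus", "species")}


def build_community(config: CommunityConfig, rng: np.random.Generator) -> CommunityTruth:
    """Generate taxonomy, target genomes and reference relatives.

    Each target gets its own phylum-to-species lineage under a shared
    root.  A reference relative at level L shares the target's lineage
    down to (and including) the rank-L node and carries its own chain
    below it; its sequence is the target mutated at the level-L
    divergence.  Read/contig collections are left empty — see
    :func:`generate_community_data`.
    """
    config.validate()
    levels = config.resolved_levels()
    covs = config.resolved_coverages()

    nodes: dict[str, TaxonNode] = {
        "root": TaxonNode("root", "root", "root", None),
        "sk": TaxonNode("sk", "Synthetica", "superkingdom", "root"),
    }
    targets: dict[str, Genome] = {}
    references: dict[str, Genome] = {}
    reference_level: dict[str, str] = {}
    coverage: dict[str, float] = {}

    ladder = ("phylum", "class", "order", "family", "genus", "species")
    for i in range(config.n_targets):
        prefix = f"T{i + 1}"
        parent = "sk"
        for rank in ladder:
            tid = f"{prefix}.{rank}"
            nodes[tid] = TaxonNode(tid, f"{prefix} {rank}", rank, parent)
            parent = tid
        target_taxon = f"{prefix}.species"

        target_id = f"target{i + 1}"
        seq = random_genome(config.genome_length, rng)
        targets[target_id] = Genome(target_id, seq, target_taxon)
        level = levels[i]
        reference_level[target_id] = level
        coverage[target_id] = covs[i]

        div = config.divergence[level]
        anchor = f"{prefix}.{level}"  # deepest node shared with every reference
        for r in range(config.n_refs_per_target):
            ref_id = f"ref{i + 1}.{r + 1}"
            ref_seq = mutate_sequence(seq, div, rng)
            if level == "species":
                ref_taxon = anchor  # same species as the target
            else:
                parent = anchor
                for rank in _CHAIN_BELOW[level]:
                    tid = f"{prefix}.R{r + 1}.{rank}"
                    nodes[tid] = TaxonNode(tid, f"{prefix} ref{r + 1} {rank}", rank, parent)
                    parent = tid
                ref_taxon = parent
            references[ref_id] = Genome(ref_id, ref_seq, ref_taxon)

    return CommunityTruth(
        taxonomy=TaxonomyTree(nodes),
        targets=targets,
        references=references,
        reference_level=reference_level,
        coverage=coverage,
    )


# ---------------------------------------------------------------------
# read and contig sampling
# ---------------------------------------------------------------------


def sample_read_pairs(
    genome_id: str,
    sequence: str,
    coverage: float,
    config: CommunityConfig,
    rng: np.random.Generator,
) -> tuple[list[ReadPairRecord], list[TruthRecord]]:
    """Sample error-bearing paired-end reads from one genome.

    The pair count is ``round(coverage * |genome| / (2 * read_length))``.
    Fragment starts are uniform; fragment lengths are Normal(insert_mean,
    insert_sd) truncated to [2*read_length, |genome| - start].  Mate 1 is
    the forward-strand fragment prefix; mate 2 the reverse complement of
    the fragment suffix; every base is substituted independently with
    probability ``error_rate``.
    """
    if coverage < 0:
        raise ConfigError("coverage must be >= 0")
    L = len(sequence)
    rl = config.read_length
    if L < config.insert_mean + 3 * config.insert_sd:
        raise ConfigError(f"genome {genome_id!r} too short for the insert distribution")
    n_pairs = int(round(coverage * L / (2 * rl)))
    pairs: list[ReadPairRecord] = []
    truths: list[TruthRecord] = []
    if n_pairs == 0:
        return pairs, truths
    starts = rng.integers(0, L - 2 * rl + 1, size=n_pairs)
    frags = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)).astype(int)
    for i in range(n_pairs):
        s = int(starts[i])
        f = int(min(max(frags[i], 2 * rl), L - s))
        m1 = sequence[s : s + rl]
        m2 = revcomp(sequence[s + f - rl : s + f])
        if config.error_rate > 0:
            m1 = mutate_sequence(m1, config.error_rate, rng)
            m2 = mutate_sequence(m2, config.error_rate, rng)
        pid = f"{genome_id}:{i}"
        pairs.append(
            ReadPairRecord(
                pair_id=pid,
                mate1=SequenceRecord(id=pid + "/1", sequence=m1),
                mate2=SequenceRecord(id=pid + "/2", sequence=m2),
            )
        )
        truths.append(TruthRecord(pid + "/1", genome_id, s, "+"))
        truths.append(TruthRecord(pid + "/2", genome_id, s + f - rl, "-"))
    return pairs, truths


def make_surrogate_contigs(
    genome_id: str,
    sequence: str,
    config: CommunityConfig,
    rng: np.random.Generator,
    min_len: int = 500,
    max_len: int = 3000,
) -> list[SequenceRecord]:
    """Error-free non-overlapping substrings standing in for assembled contigs.

    Contig lengths are uniform in [min_len, max_len]; total contig length
    approximates ``contig_fraction * |genome|`` and gaps between contigs
    are placed by a uniform Dirichlet split, so placement is uniform
    without overlap.  Returns [] when the budget cannot fit one contig.
    """
    L = len(sequence)
    budget = config.contig_fraction * L
    if budget < min_len:
        return []
    lengths: list[int] = []
    total = 0
    while total + min_len <= budget:
        ln = int(rng.integers(min_len, max_len + 1))
        remaining = int(budget - total)
        ln = min(ln, remaining)
        if ln < min_len:
            break
        lengths.append(ln)
        total += ln
    if not lengths:
        return []
    gap_total = L - total
    weights = rng.dirichlet(np.ones(len(lengths) + 1))
    gaps = np.floor(weights * gap_total).astype(int)
    gaps[0] += gap_total - int(gaps.sum())
    out: list[SequenceRecord] = []
    pos = 0
    for j, ln in enumerate(lengths):
        pos += int(gaps[j])
        out.append(
            SequenceRecord(
                id=f"{genome_id}.c{j:04d}",
                sequence=sequence[pos : pos + ln],
                description=f"origin={genome_id}:{pos}",
            )
        )
        pos += ln
    return out


def generate_community_data(
    config: CommunityConfig, rng: np.random.Generator | None = None
) -> CommunityTruth:
    """Full dataset: community plus reads, ground truth and contigs."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    community = build_community(config, rng)
    for target_id in sorted(community.targets):
        genome = community.targets[target_id]
        pairs, truths = sample_read_pairs(
            target_id, genome.sequence, community.coverage[target_id], config, rng
        )
        community.read_pairs.extend(pairs)
        community.truth.extend(truths)
        community.contigs.extend(
            make_surrogate_contigs(target_id, genome.sequence, config, rng)
        )
    return community
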