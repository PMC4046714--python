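"""Pipeline orchestration: simulate -> bin -> annotate -> evaluate.

Every stage has an in-memory core (used directly by library callers and
tests) and a thin file wrapper that reads/writes the self-describing TSV
artifacts, so stages can be rerun individually from disk.  A single
global seed is fanned out per stage by stable hashing, making stage
reruns reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import annotation as anno
from . import clustering as clus
from . import evaluation as ev
from . import seqio
from . import simulate as sim
from . import virtual_contigs as vc1
from .taxonomy import TaxonomyTree, dump_taxonomy, load_taxonomy

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the pipeline with their conventional defaults.

    w = 36 is the shortest species-unique w-mer length; q = 5 profiles
    drive clustering of virtual contigs of at least 10 kb while q = 4
    profiles attach shorter ones; reads join contigs at >= 95% identity
    and only contigs of >= 500 bp count.
    """

    out_dir: Path = Path("mcta_out")
    # simulate
    n_targets: int = 6
    genome_length: int = 100_000
    coverage: float = 15.0
    contig_fraction: float = 0.6
    reference_levels: Sequence[str] | None = None
    n_refs_per_target: int = 2
    error_rate: float = 0.01
    read_length: int = 75
    insert_mean: float = 250.0
    insert_sd: float = 50.0
    # phase 1
    w: int = 36
    min_identity: float = 0.95
    min_contig_len: int = 500
    align_seed_k: int = 16
    min_shared: int = 1
    repeat_cap: int = 50
    # phase 2
    q_long: int = 5
    q_short: int = 4
    length_threshold: int = 10_000
    k: int | str = "auto"  # cluster count, or "auto" for a silhouette scan
    k_max: int = 16
    # phase 3
    hit_source: str = "builtin"  # builtin | imported
    hits_path: Path | None = None
    hit_seed_k: int = 12
    min_hit_fraction: float = 0.05
    seed: int = 0
    # optional explicit input paths (default: artifacts inside out_dir)
    inputs: dict = field(default_factory=dict)

    def path(self, name: str) -> Path:
        default = self.out_dir / name
        return Path(self.inputs.get(name, default))

    def validate(self) -> None:
        if self.q_long <= self.q_short:
            raise ValueError("q_long must exceed q_short")
        for attr in ("w", "min_contig_len", "length_threshold", "align_seed_k", "hit_seed_k"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.hit_source not in ("builtin", "imported"):
            raise ValueError("hit_source must be 'builtin' or 'imported'")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of (seed, stage name)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------
# in-memory stage cores
# ---------------------------------------------------------------------


@dataclass
class BinResult:
    vcs: list[vc1.VirtualContig]
    models: list[clus.ClusterModel]
    vc_to_cluster: dict[str, str]
    read_to_contig: dict[str, str]
    unassigned_reads: list[str]
    vc_length_class: dict[str, str]  # vc_id -> "long" | "short"


def _auto_k(profiles, k_max: int, seed: int) -> int:
    """Pick K in [2, k_max] maximizing the mean silhouette under Spearman
    distance; falls back to 1 when fewer than 3 profiles exist."""
    n = len(profiles)
    if n < 3:
        return 1
    ranked = clus._rank_rows(np.stack([p.values for p in profiles]))
    D = clus._rank_distances(ranked, ranked)
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = clus.kmeans_spearman(profiles, k, seed=seed)
        s = _mean_silhouette(D, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = D.shape[0]
    vals = []
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        a = D[i, same].mean() if same.any() else 0.0
        bs = [D[i, labels == l].mean() for l in set(labels) if l != labels[i]]
        if not bs:
            return -np.inf
        b = min(bs)
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


def bin_stage(
    read_pairs: Sequence[seqio.ReadPairRecord],
    contigs: Sequence[seqio.SequenceRecord],
    cfg: PipelineConfig,
) -> BinResult:
    """Phases 1 and 2: virtual contigs, then composition clustering."""
    reads = [m for p in read_pairs for m in (p.mate1, p.mate2)]
    read_seqs = {r.id: r.sequence for r in reads}
    contig_seqs = {c.id: c.sequence for c in contigs}

    assignment, unassigned = vc1.assign_reads_to_contigs(
        reads,
        contigs,
        min_identity=cfg.min_identity,
        min_contig_len=cfg.min_contig_len,
        seed_k=cfg.align_seed_k,
    )
    eligible = [c.id for c in contigs if len(c.sequence) >= cfg.min_contig_len]
    clusters = vc1.build_initial_clusters(assignment, unassigned, eligible)
    logger.info("phase1: %d initial clusters (%d contig-seeded)", len(clusters), len(eligible))
    vcs = vc1.merge_by_shared_wmers(
        clusters,
        read_seqs,
        contig_seqs,
        w=cfg.w,
        min_shared=cfg.min_shared,
        repeat_cap=cfg.repeat_cap,
    )
    logger.info("phase1: %d virtual contigs", len(vcs))

    long_vcs, short_vcs = clus.split_by_length(vcs, cfg.length_threshold)
    logger.info("phase2: %d long / %d short virtual contigs", len(long_vcs), len(short_vcs))
    length_class = {v.vc_id: "long" for v in long_vcs}
    length_class.update({v.vc_id: "short" for v in short_vcs})

    if not long_vcs:
        # degenerate input: nothing to seed K-means; pool everything
        logger.warning("phase2: no long virtual contigs; pooling all into one cluster")
        models = clus.build_cluster_models(vcs, np.zeros(len(vcs), dtype=int))
        vc_to_cluster = {v.vc_id: models[0].cluster_id for v in vcs}
        return BinResult(vcs, models, vc_to_cluster, assignment, unassigned, length_class)

    profiles = [clus.composition_profile(v, cfg.q_long) for v in long_vcs]
    k2seed = stage_seed(cfg.seed, "phase2")
    if cfg.k == "auto":
        k = _auto_k(profiles, cfg.k_max, k2seed)
        logger.info("phase2: auto-selected K=%d", k)
    else:
        k = min(int(cfg.k), len(long_vcs))
    labels = clus.kmeans_spearman(profiles, k, seed=k2seed)
    models = clus.build_cluster_models(long_vcs, labels)
    vc_to_cluster: dict[str, str] = {}
    for m in models:
        for vid in m.vc_ids:
            vc_to_cluster[vid] = m.cluster_id
    if short_vcs:
        vc_to_cluster.update(clus.assign_short_vcs(short_vcs, models))
    return BinResult(vcs, models, vc_to_cluster, assignment, unassigned, length_class)


@dataclass
class AnnotateResult:
    records: list[anno.ClusterAnnotationRecord]
    merged_records: list[anno.ClusterAnnotationRecord]
    cluster_id_map: dict[str, str]
    read_annotations: dict[str, str]
    read_to_cluster: dict[str, str]


def annotate_stage(
    binres: BinResult,
    contigs: Sequence[seqio.SequenceRecord],
    db: anno.ReferenceDB,
    tree: TaxonomyTree,
    cfg: PipelineConfig,
    imported_hits: Mapping[str, tuple[str, float]] | None = None,
) -> AnnotateResult:
    """Phase 3: annotate clusters, merge species-level duplicates, propagate."""
    contig_by_id = {c.id: c for c in contigs}
    members: dict[str, list[vc1.VirtualContig]] = {}
    for v in binres.vcs:
        members.setdefault(binres.vc_to_cluster[v.vc_id], []).append(v)
    records = []
    for cid in sorted(members):
        cluster_contigs = [
            contig_by_id[c] for v in members[cid] for c in sorted(v.contig_ids)
        ]
        records.append(
            anno.annotate_cluster(
                cid,
                cluster_contigs,
                db,
                tree,
                imported_hits=imported_hits,
                min_hit_fraction=cfg.min_hit_fraction,
            )
        )
    merged, id_map = anno.merge_clusters_by_annotation(records, tree)
    n_annot = sum(r.taxon_id != anno.UNASSIGNED for r in merged)
    logger.info("phase3: %d/%d final clusters annotated", n_annot, len(merged))
    cluster_reads: dict[str, set[str]] = {r.cluster_id: set() for r in merged}
    read_to_cluster: dict[str, str] = {}
    for v in binres.vcs:
        final = id_map[binres.vc_to_cluster[v.vc_id]]
        cluster_reads[final] |= v.read_ids
        for rid in v.read_ids:
            read_to_cluster[rid] = final
    read_annotations = anno.propagate_to_reads(cluster_reads, merged)
    return AnnotateResult(records, merged, id_map, read_annotations, read_to_cluster)


# ---------------------------------------------------------------------
# file-based stage wrappers
# ---------------------------------------------------------------------


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_simulate(cfg: PipelineConfig) -> sim.CommunityTruth:
    try:
        community_cfg = sim.CommunityConfig(
            n_targets=cfg.n_targets,
            genome_length=cfg.genome_length,
            coverages=[cfg.coverage] * cfg.n_targets,
            reference_levels=cfg.reference_levels,
            n_refs_per_target=cfg.n_refs_per_target,
            read_length=cfg.read_length,
            error_rate=cfg.error_rate,
            insert_mean=cfg.insert_mean,
            insert_sd=cfg.insert_sd,
            contig_fraction=cfg.contig_fraction,
            seed=stage_seed(cfg.seed, "simulate"),
        )
        community = sim.generate_community_data(community_cfg)
        out = cfg.out_dir
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "reads_1.fastq", "w") as f1, open(out / "reads_2.fastq", "w") as f2:
            seqio.write_fastq((p.mate1 for p in community.read_pairs), f1)
            seqio.write_fastq((p.mate2 for p in community.read_pairs), f2)
        with open(out / "contigs.fasta", "w") as fh:
            seqio.write_fasta(community.contigs, fh)
        with open(out / "references.fasta", "w") as fh:
            seqio.write_fasta(
                [
                    seqio.SequenceRecord(id=g.genome_id, sequence=g.sequence)
                    for g in community.references.values()
                ],
                fh,
            )
        with open(out / "taxonomy.tsv", "w") as fh:
            dump_taxonomy(community.taxonomy, fh)
        with open(out / "truth.tsv", "w") as fh:
            seqio.write_truth(community.truth, fh)
        lines = ["#genome_id\trole\ttaxon_id\treference_level\tcoverage"]
        for gid, g in sorted(community.targets.items()):
            lines.append(
                f"{gid}\ttarget\t{g.taxon_id}\t{community.reference_level[gid]}"
                f"\t{community.coverage[gid]}"
            )
        for gid, g in sorted(community.references.items()):
            lines.append(f"{gid}\treference\t{g.taxon_id}\t-\t-")
        _write(out / "genomes_meta.tsv", "\n".join(lines) + "\n")
        logger.info(
            "simulate: %d pairs, %d contigs, %d references",
            len(community.read_pairs),
            len(community.contigs),
            len(community.references),
        )
        return community
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc


def run_bin(cfg: PipelineConfig) -> BinResult:
    try:
        pairs = seqio.read_fastq_pairs(cfg.path("reads_1.fastq"), cfg.path("reads_2.fastq"))
        contigs = seqio.read_fasta(cfg.path("contigs.fasta"))
    except Exception as exc:
        raise PipelineStageError("phase1", exc) from exc
    try:
        binres = bin_stage(pairs, contigs, cfg)
    except Exception as exc:
        raise PipelineStageError("phase2", exc) from exc
    out = cfg.out_dir
    rows = ["#vc_id\tmember_type\tmember_id"]
    srows = ["#vc_id\tn_reads\tn_contigs\testimated_length\tlength_class\tcluster_id"]
    for v in binres.vcs:
        for cid in sorted(v.contig_ids):
            rows.append(f"{v.vc_id}\tcontig\t{cid}")
        for rid in sorted(v.read_ids):
            rows.append(f"{v.vc_id}\tread\t{rid}")
        srows.append(
            f"{v.vc_id}\t{len(v.read_ids)}\t{len(v.contig_ids)}\t{v.estimated_length}"
            f"\t{binres.vc_length_class[v.vc_id]}\t{binres.vc_to_cluster[v.vc_id]}"
        )
    _write(out / "virtual_contigs.tsv", "\n".join(rows) + "\n")
    _write(out / "vc_summary.tsv", "\n".join(srows) + "\n")
    crows = ["#cluster_id\tvc_id\tlength_class"]
    for v in binres.vcs:
        crows.append(
            f"{binres.vc_to_cluster[v.vc_id]}\t{v.vc_id}\t{binres.vc_length_class[v.vc_id]}"
        )
    _write(out / "clusters.tsv", "\n".join(crows) + "\n")
    return binres


def load_bin_result(cfg: PipelineConfig) -> BinResult:
    """Rebuild the binning state needed by annotation from stage artifacts.

    Membership and cluster assignment are read back from
    ``virtual_contigs.tsv`` and ``clusters.tsv``; w-mer summaries are not
    reloaded (annotation does not use them).
    """
    vcs: dict[str, vc1.VirtualContig] = {}
    for line in Path(cfg.path("virtual_contigs.tsv")).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        vc_id, member_type, member_id = line.split("\t")
        vc = vcs.setdefault(vc_id, vc1.VirtualContig(vc_id, set(), set(), set(), 0))
        (vc.contig_ids if member_type == "contig" else vc.read_ids).add(member_id)
    vc_to_cluster: dict[str, str] = {}
    length_class: dict[str, str] = {}
    for line in Path(cfg.path("clusters.tsv")).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cluster_id, vc_id, lclass = line.split("\t")
        vc_to_cluster[vc_id] = cluster_id
        length_class[vc_id] = lclass
    return BinResult(
        vcs=[vcs[v] for v in sorted(vcs)],
        models=[],
        vc_to_cluster=vc_to_cluster,
        read_to_contig={},
        unassigned_reads=[],
        vc_length_class=length_class,
    )


def run_annotate(cfg: PipelineConfig, binres: BinResult) -> AnnotateResult:
    try:
        refs = seqio.read_fasta(cfg.path("references.fasta"))
        tree = load_taxonomy(cfg.path("taxonomy.tsv"))
        taxa = _load_genome_taxa(cfg.path("genomes_meta.tsv"))
        db = anno.ReferenceDB(
            {r.id: r.sequence for r in refs},
            {r.id: taxa[r.id] for r in refs},
            tree,
            seed_k=cfg.hit_seed_k,
        )
        imported = None
        if cfg.hit_source == "imported":
            if cfg.hits_path is None:
                raise ValueError("hit_source=imported requires hits_path")
            imported = anno.best_hits_from_table(seqio.read_tabular_hits(cfg.hits_path))
        contigs = seqio.read_fasta(cfg.path("contigs.fasta"))
        res = annotate_stage(binres, contigs, db, tree, cfg, imported_hits=imported)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("phase3", exc) from exc
    out = cfg.out_dir
    arows = ["#cluster_id\ttaxon_id\trank\tname\tn_contigs_hit\tn_contigs_total"]
    for r in res.merged_records:
        if r.taxon_id == anno.UNASSIGNED:
            rank = name = "-"
        else:
            node = tree.node(r.taxon_id)
            rank, name = node.rank, node.name
        arows.append(
            f"{r.cluster_id}\t{r.taxon_id}\t{rank}\t{name}"
            f"\t{len(r.contig_hits)}\t{r.n_contigs_total}"
        )
    _write(out / "annotation.tsv", "\n".join(arows) + "\n")
    rrows = ["#read_id\tfinal_cluster_id\ttaxon_id"]
    for rid in sorted(res.read_annotations):
        rrows.append(f"{rid}\t{res.read_to_cluster[rid]}\t{res.read_annotations[rid]}")
    _write(out / "read_assignments.tsv", "\n".join(rrows) + "\n")
    return res


def _load_genome_taxa(path: Path) -> dict[str, str]:
    taxa: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        taxa[fields[0]] = fields[2]
    return taxa


def _load_meta(path: Path) -> tuple[dict[str, str], dict[str, str]]:
    """(genome -> taxon, target genome -> reference level)."""
    taxa: dict[str, str] = {}
    levels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        gid, role, taxon, level, _cov = line.split("\t")
        taxa[gid] = taxon
        if role == "target":
            levels[gid] = level
    return taxa, levels


def run_evaluate(cfg: PipelineConfig) -> ev.EvaluationReport:
    try:
        tree = load_taxonomy(cfg.path("taxonomy.tsv"))
        truth = {t.read_id: t.genome_id for t in seqio.read_truth(cfg.path("truth.tsv"))}
        taxa, levels = _load_meta(cfg.path("genomes_meta.tsv"))
        read_annotations: dict[str, str] = {}
        read_to_cluster: dict[str, str | None] = {}
        for line in Path(cfg.path("read_assignments.tsv")).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            rid, cid, taxon = line.split("\t")
            read_annotations[rid] = taxon
            read_to_cluster[rid] = cid
        report = ev.evaluate(read_annotations, read_to_cluster, truth, taxa, levels, tree)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("evaluate", exc) from exc
    rows = ["#section\tkey\toutcome\tvalue"]
    for level, fr in sorted(report.outcome_fractions.items()):
        for outcome, val in fr.items():
            rows.append(f"annotation\t{level}\t{outcome}\t{val:.6f}")
    rows.append(f"binning\tprecision\t-\t{report.precision}")
    rows.append(f"binning\tsensitivity\t-\t{report.sensitivity}")
    n_disc = sum(report.discovered.values())
    rows.append(f"discovery\tn_discovered\t-\t{n_disc}")
    rows.append(f"discovery\tn_species\t-\t{len(report.discovered)}")
    _write(cfg.out_dir / "report.tsv", "\n".join(rows) + "\n")
    return report


def run_pipeline(cfg: PipelineConfig) -> ev.EvaluationReport:
    """Run every stage in order; identical config + seed gives identical
    artifacts."""
    cfg.validate()
    run_simulate(cfg)
    binres = run_bin(cfg)
    run_annotate(cfg, binres)
    return run_evaluate(cfg)
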