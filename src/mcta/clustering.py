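"""Phase 2: q-mer composition profiles and Spearman-distance clustering.

The q-mer spectrum of a genome is a compositional signature: fragments of
the same genome have similar 4/5-mer distributions.  Because read
coverage is uneven, a virtual contig's spectrum is estimated over its
*distinct* canonical w-mer set rather than over raw reads, which removes
duplicate-coverage bias exactly.

Long virtual contigs (estimated length >= 10 kb) are clustered by
K-means under the Spearman distance (1 - rank correlation) of their
5-mer profiles; short ones are attached afterwards to the nearest
centroid by their 4-mer profiles, since 5-mer spectra of short fragments
are too noisy to steer the clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .kmers import count_qmers_in_wmers, profile_dimension
from .virtual_contigs import VirtualContig

logger = logging.getLogger(__name__)


@dataclass
class CompositionProfile:
    """Normalized canonical q-mer frequency vector (dim 136 for q=4, 512 for q=5),
    indexed by lexicographically sorted canonical q-mer."""

    q: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (profile_dimension(self.q),):
            raise ValueError(
                f"profile for q={self.q} must have dimension {profile_dimension(self.q)}"
            )
        if (self.values < 0).any():
            raise ValueError("profile entries must be >= 0")
        total = self.values.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("profile must sum to 1")


@dataclass
class ClusterModel:
    """One composition cluster: members plus 5-mer and 4-mer centroids."""

    cluster_id: str
    vc_ids: list[str]
    centroid5: CompositionProfile
    centroid4: CompositionProfile


def composition_profile(vc: VirtualContig, q: int) -> CompositionProfile:
    """Canonical q-mer frequency profile of a virtual contig.

    Counts every q-mer window inside each distinct canonical w-mer of the
    summary, maps windows to canonical q-mers, and normalizes.
    """
    if not vc.wmers:
        raise ValueError(f"virtual contig {vc.vc_id!r} has an empty w-mer summary")
    counts = count_qmers_in_wmers(vc.wmers, q)
    return CompositionProfile(q=q, values=counts / counts.sum())


def spearman_distance(p: CompositionProfile, r: CompositionProfile) -> float:
    """1 - Spearman rank correlation of two same-q profiles; range [0, 2].

    A constant profile has no rank variance; its correlation with anything
    is taken as 0 (distance 1) and the event is logged.
    """
    if p.q != r.q:
        raise ValueError("profiles must share q")
    return float(_rank_distances(_rank_rows(p.values[None, :]), _rank_rows(r.values[None, :]))[0, 0])


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    """Center and L2-normalize average ranks per row; zero-variance rows -> 0."""
    ranks = rankdata(mat, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    degenerate = norms[:, 0] == 0.0
    if degenerate.any():
        logger.warning("constant profile(s) encountered; Spearman distance defaults to 1")
        norms[degenerate] = 1.0
    return ranks / norms


def _rank_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Spearman distances between pre-normalized rank matrices."""
    return np.clip(1.0 - a @ b.T, 0.0, 2.0)


def _centroids_of(mat: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    out = np.empty((k, mat.shape[1]))
    for j in range(k):
        m = mat[labels == j].mean(axis=0)
        out[j] = m / m.sum()
    return out


def _objective_of(mat: np.ndarray, ranked: np.ndarray, labels: np.ndarray, k: int) -> float:
    cd = _rank_distances(ranked, _rank_rows(_centroids_of(mat, labels, k)))
    return float(cd[np.arange(mat.shape[0]), labels].sum())


def _lloyd(
    mat: np.ndarray,
    ranked: np.ndarray,
    centroids: np.ndarray,
    k: int,
    max_iter: int,
    history: list[float] | None,
) -> tuple[np.ndarray, float]:
    n = mat.shape[0]
    labels: np.ndarray | None = None
    prev_objective = np.inf
    centroids = centroids.copy()
    for _ in range(max_iter):
        cd = _rank_distances(ranked, _rank_rows(centroids))
        new_labels = cd.argmin(axis=1)
        # reseed empty clusters with the globally worst-fit profile
        for j in range(k):
            if not (new_labels == j).any():
                worst = int(np.argmax(cd[np.arange(n), new_labels]))
                new_labels[worst] = j
        objective = float(cd[np.arange(n), new_labels].sum())
        if labels is not None and objective > prev_objective + 1e-12:
            logger.warning("K-means objective increased; stopping at previous assignment")
            break
        if history is not None:
            history.append(objective)
        converged = labels is not None and (new_labels == labels).all()
        labels = new_labels
        prev_objective = objective
        if converged:
            break
        centroids = _centroids_of(mat, labels, k)
    assert labels is not None
    return labels, prev_objective


def _farthest_point_centers(pair_d: np.ndarray, k: int) -> list[int]:
    centers = [int(np.argmax(pair_d.sum(axis=1)))]
    while len(centers) < k:
        mind = pair_d[:, centers].min(axis=1)
        mind[centers] = -1.0
        centers.append(int(np.argmax(mind)))
    return centers


def _bisect(mat: np.ndarray, ranked: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """2-means on a subset; returns a 0/1 sub-label per element of idx."""
    sub_d = _rank_distances(ranked[idx], ranked[idx])
    centers = _farthest_point_centers(sub_d, 2)
    sub_labels, _ = _lloyd(mat[idx], ranked[idx], mat[idx][centers], 2, 50, None)
    return sub_labels


def kmeans_spearman(
    profiles: Sequence[CompositionProfile],
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    objective_history: list[float] | None = None,
) -> np.ndarray:
    """K-means under Spearman distance; returns an integer label per profile.

    Initialization is deterministic farthest-point seeding: the first
    center is the profile with the largest total distance to all others,
    each subsequent one the profile farthest from the chosen set.  The
    update step takes the renormalized arithmetic mean of member
    frequency vectors (there is no closed-form Spearman centroid); the
    within-cluster objective is tracked and, in the rare event the mean
    update increases it, the run stops at the previous assignment.

    Farthest-point seeding can trap Lloyd iterations in a poor local
    optimum when one tight group is internally more spread than the gap
    between two others.  After convergence a deterministic merge-split
    refinement therefore tries, for every cluster pair and every third
    cluster, merging the pair while bisecting the third, re-polishes the
    best candidate with Lloyd iterations, and accepts it only when the
    objective strictly decreases.  The whole procedure is deterministic
    for fixed inputs (``seed`` is accepted for interface stability).
    """
    n = len(profiles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    mat = np.stack([p.values for p in profiles])
    ranked = _rank_rows(mat)
    pair_d = _rank_distances(ranked, ranked)

    centers = _farthest_point_centers(pair_d, k)
    labels, objective = _lloyd(mat, ranked, mat[centers], k, max_iter, objective_history)

    for _ in range(2 * k):  # refinement rounds
        best: tuple[float, np.ndarray] | None = None
        for a in range(k):
            for b in range(a + 1, k):
                for c in range(k):
                    if c == a or c == b:
                        continue
                    idx_c = np.flatnonzero(labels == c)
                    if idx_c.size < 2:
                        continue
                    cand = labels.copy()
                    cand[cand == b] = a
                    cand[idx_c[_bisect(mat, ranked, idx_c) == 1]] = b
                    if len(set(cand.tolist())) < k:
                        continue
                    obj = _objective_of(mat, ranked, cand, k)
                    if best is None or obj < best[0] - 1e-12:
                        best = (obj, cand)
        if best is None or best[0] >= objective - 1e-9:
            break
        polish_history: list[float] = []
        labels, objective = _lloyd(
            mat, ranked, _centroids_of(mat, best[1], k), k, max_iter, polish_history
        )
        if objective_history is not None:
            objective_history.extend(polish_history)
    return labels


def split_by_length(
    vcs: Sequence[VirtualContig], threshold: int = 10_000
) -> tuple[list[VirtualContig], list[VirtualContig]]:
    """Partition virtual contigs into (long, short); long iff estimated
    length >= threshold (10 kb by default)."""
    long_vcs = [v for v in vcs if v.estimated_length >= threshold]
    short_vcs = [v for v in vcs if v.estimated_length < threshold]
    return long_vcs, short_vcs


def build_cluster_models(
    vcs: Sequence[VirtualContig], labels: np.ndarray
) -> list[ClusterModel]:
    """Assemble cluster models from K-means labels over long virtual contigs.

    The 5-mer centroid is the renormalized mean of member profiles; the
    4-mer centroid used for short-VC attachment is the estimated-length-
    weighted mean of member 4-mer profiles, renormalized.
    """
    models: list[ClusterModel] = []
    for j in sorted(set(int(l) for l in labels)):
        members = [vcs[i] for i in range(len(vcs)) if labels[i] == j]
        p5 = np.stack([composition_profile(v, 5).values for v in members]).mean(axis=0)
        weights = np.array([float(v.estimated_length) for v in members])
        p4s = np.stack([composition_profile(v, 4).values for v in members])
        p4 = (p4s * weights[:, None]).sum(axis=0) / weights.sum()
        models.append(
            ClusterModel(
                cluster_id=f"cl{j:03d}",
                vc_ids=[v.vc_id for v in members],
                centroid5=CompositionProfile(5, p5 / p5.sum()),
                centroid4=CompositionProfile(4, p4 / p4.sum()),
            )
        )
    return models


def assign_short_vcs(
    short_vcs: Sequence[VirtualContig], models: Sequence[ClusterModel]
) -> dict[str, str]:
    """Attach each short virtual contig to the nearest 4-mer centroid.

    Ties go to the smallest cluster_id.
    """
    if not models:
        raise ValueError("no cluster models to attach to")
    ordered = sorted(models, key=lambda m: m.cluster_id)
    cent4 = _rank_rows(np.stack([m.centroid4.values for m in ordered]))
    out: dict[str, str] = {}
    for vc in short_vcs:
        prof = composition_profile(vc, 4)
        d = _rank_distances(_rank_rows(prof.values[None, :]), cent4)[0]
        out[vc.vc_id] = ordered[int(np.argmin(d))].cluster_id
    return out
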