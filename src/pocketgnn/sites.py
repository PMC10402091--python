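"""From per-atom scores to discrete ranked binding sites.

Surface atoms scoring strictly above a threshold (0.3 by default) are
grouped by average-linkage agglomerative clustering on Euclidean distance,
the dendrogram is cut at a fixed linkage distance, tiny clusters are
dropped, each site is scored S_S = sum of its members' S_a squared, and its
center is the volume centroid of the members' convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError

from .nn import ScoredAtoms
from .types import InvalidInputError

__all__ = [
    "BindingSite",
    "cluster_scored_atoms",
    "score_site",
    "site_center",
    "rank_sites",
    "predict_sites",
]

SCORE_THRESHOLD = 0.3     # strict ">": atoms scoring exactly 0.3 are excluded
LINKAGE_CUTOFF = 7.0      # Å, dendrogram cut distance (order of pocket diameters)
MIN_CLUSTER_SIZE = 3      # smaller clusters are noise / degenerate hulls


@dataclass
class BindingSite:
    atom_indices: np.ndarray      # protein-atom indices of the members
    member_scores: np.ndarray
    site_score: float             # S_S = sum S_a^2
    center: np.ndarray            # 3-vector, Å
    rank: int                     # 1-based


def cluster_scored_atoms(
    scored: ScoredAtoms,
    coords: np.ndarray,
    score_threshold: float = SCORE_THRESHOLD,
    linkage_cutoff: float = LINKAGE_CUTOFF,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> list[np.ndarray]:
    """Average-linkage clusters (as index arrays into ``scored``) of the
    atoms scoring strictly above the threshold. May be empty."""
    coords = np.asarray(coords, float)
    if len(coords) != len(scored.scores):
        raise InvalidInputError("scores and coordinates are misaligned")
    sel = np.flatnonzero(scored.scores > score_threshold)
    if sel.size == 0:
        return []
    if sel.size == 1:
        clusters = [sel]
    else:
        Z = linkage(coords[sel], method="average")
        labels = fcluster(Z, t=linkage_cutoff, criterion="distance")
        clusters = [sel[labels == lab] for lab in np.unique(labels)]
    return [c for c in clusters if c.size >= min_cluster_size]


def score_site(member_scores: np.ndarray) -> float:
    """Site score S_S = sum of squared member atom scores (additive)."""
    member_scores = np.asarray(member_scores, float)
    if member_scores.size == 0:
        raise InvalidInputError("cannot score an empty site")
    return float(np.sum(member_scores**2))


def site_center(member_coords: np.ndarray) -> np.ndarray:
    """Volume centroid of the members' convex hull.

    Degenerate inputs (fewer than 4 points, or coplanar/collinear sets with
    no 3D hull) fall back to the arithmetic mean of the coordinates.
    """
    pts = np.atleast_2d(np.asarray(member_coords, float))
    if len(pts) < 4:
        return pts.mean(axis=0)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return pts.mean(axis=0)
    # decompose the hull into tetrahedra fanned from an interior point
    apex = pts[hull.vertices].mean(axis=0)
    total_vol = 0.0
    centroid = np.zeros(3)
    for simplex in hull.simplices:
        a, b, c = pts[simplex]
        vol = abs(np.dot(a - apex, np.cross(b - apex, c - apex))) / 6.0
        centroid += vol * (a + b + c + apex) / 4.0
        total_vol += vol
    if total_vol <= 0:
        return pts.mean(axis=0)
    return centroid / total_vol


def rank_sites(
    clusters: list[np.ndarray],
    scored: ScoredAtoms,
    coords: np.ndarray,
) -> list[BindingSite]:
    """Rank clusters by descending S_S; ties broken by larger member count,
    then by lowest member atom index (fully deterministic)."""
    sites = []
    for cl in clusters:
        ms = scored.scores[cl]
        sites.append(
            (
                score_site(ms),
                len(cl),
                -int(scored.atom_indices[cl].min()),
                cl,
                ms,
            )
        )
    sites.sort(key=lambda s: (s[0], s[1], s[2]), reverse=True)
    out = []
    for rank, (ss, _, _, cl, ms) in enumerate(sites, start=1):
        out.append(
            BindingSite(
                atom_indices=scored.atom_indices[cl],
                member_scores=ms,
                site_score=ss,
                center=site_center(coords[cl]),
                rank=rank,
            )
        )
    return out


def predict_sites(
    scored: ScoredAtoms,
    coords: np.ndarray,
    score_threshold: float = SCORE_THRESHOLD,
    linkage_cutoff: float = LINKAGE_CUTOFF,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> list[BindingSite]:
    """Threshold + cluster + score + rank, in one call.

    ``coords`` are the coordinates of the scored (surface) atoms, aligned
    with ``scored.scores``.
    """
    clusters = cluster_scored_atoms(
        scored, coords, score_threshold, linkage_cutoff, min_cluster_size
    )
    return rank_sites(clusters, scored, coords)
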