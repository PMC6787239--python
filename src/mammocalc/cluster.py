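"""Noise filtering of candidate spots and DBSCAN grouping into clusters.

Isolated calcifications are not clinically significant; only spatially dense
groups are counted. Candidates are first filtered on size, shape and ridge
response (vessel walls and fibrous strands produce elongated or
ridge-coincident detections), then grouped with DBSCAN in physical (mm)
coordinates. DBSCAN noise points are the discarded isolated spots.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN

from .types import BreastMask, CandidateSpot, Cluster, ClusterSet

__all__ = [
    "shape_filter",
    "dbscan_group",
    "dbscan_points",
    "count_clusters_per_woman",
]


def shape_filter(
    spots: list[CandidateSpot],
    min_area_px: int = 2,
    max_area_px: int = 80,
    max_eccentricity: float = 0.95,
    line_map: np.ndarray | None = None,
    line_veto: float = 0.5,
) -> tuple[list[CandidateSpot], dict[str, int]]:
    """Keep spots whose size, shape and appearance match microcalcifications.

    A spot survives when ``min_area_px <= area <= max_area_px``, its
    eccentricity is at most ``max_eccentricity``, and (when a ridge-response
    map is given) the mean ridge response over its pixels is below
    ``line_veto`` — spots riding on a contiguous linear structure are vetoed,
    while beaded vessel-wall calcifications whose specks stand apart from the
    ridge response pass. Returns the survivors and a dict of removal counts
    keyed by reason (``area``, ``eccentricity``, ``line``).
    """
    if min_area_px > max_area_px:
        raise ValueError("min_area_px must be <= max_area_px")
    if not 0 < max_eccentricity <= 1:
        raise ValueError("max_eccentricity must be in (0, 1]")
    survivors: list[CandidateSpot] = []
    removed = {"area": 0, "eccentricity": 0, "line": 0}
    for spot in spots:
        if not min_area_px <= spot.area_px <= max_area_px:
            removed["area"] += 1
            continue
        if spot.eccentricity > max_eccentricity:
            removed["eccentricity"] += 1
            continue
        if line_map is not None and spot.coords.size:
            ridge_mean = float(line_map[spot.coords[:, 0], spot.coords[:, 1]].mean())
            if ridge_mean >= line_veto:
                removed["line"] += 1
                continue
        survivors.append(spot)
    return survivors, removed


def dbscan_points(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Run DBSCAN on raw points; returns labels (-1 = noise).

    Points are clustered in the units they are given in; callers pass mm
    coordinates with ``eps`` in mm. Input order is preserved in the returned
    labels.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_


def dbscan_group(
    spots: list[CandidateSpot],
    eps_mm: float = 5.0,
    min_pts: int = 3,
    spacing_mm: float = 0.05,
    n_filtered_by_shape: int = 0,
) -> ClusterSet:
    """Group surviving spots into clusters with DBSCAN.

    Spot centroids are converted to mm and clustered with Euclidean
    ``eps = eps_mm`` and ``min_samples = min_pts``. Spots are sorted by
    (row, col) before clustering so border-point assignment follows a
    deterministic scan order and the partition is invariant to the order in
    which spots are supplied. DBSCAN noise points are counted as discarded
    isolated spots. Cluster hull areas are reported in mm^2 (0 for degenerate
    hulls of fewer than 3 non-collinear points).
    """
    if eps_mm <= 0:
        raise ValueError("eps_mm must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if not spots:
        return ClusterSet(clusters=[], n_isolated_discarded=0,
                          n_filtered_by_shape=n_filtered_by_shape)
    order = sorted(range(len(spots)), key=lambda i: spots[i].centroid_rc)
    pts_mm = np.array([spots[i].centroid_rc for i in order], dtype=float) * spacing_mm
    labels = dbscan_points(pts_mm, eps=eps_mm, min_pts=min_pts)

    clusters: list[Cluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        member_pos = np.flatnonzero(labels == lab)
        members = [order[p] for p in member_pos]
        pts = pts_mm[member_pos]
        centroid_mm = pts.mean(axis=0)
        hull_area = 0.0
        if len(pts) >= 3:
            try:
                hull_area = float(ConvexHull(pts).volume)  # 2-D: volume == area
            except QhullError:
                hull_area = 0.0  # collinear points
        clusters.append(
            Cluster(
                member_indices=sorted(members),
                centroid_rc=(centroid_mm[0] / spacing_mm, centroid_mm[1] / spacing_mm),
                hull_area_mm2=hull_area,
            )
        )
    n_noise = int((labels == -1).sum())
    return ClusterSet(clusters=clusters, n_isolated_discarded=n_noise,
                      n_filtered_by_shape=n_filtered_by_shape)


def count_clusters_per_woman(left: ClusterSet | None, right: ClusterSet | None) -> int:
    """Total cluster count over both breasts (the study's exposure variable).

    Women lacking either MLO view are excluded from analysis, so a missing
    side is an error rather than a zero.
    """
    if left is None or right is None:
        raise ValueError("missing side: both left and right cluster sets are required")
    return left.n_clusters + right.n_clusters
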