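"""Spot filtering and DBSCAN grouping, checked against a brute-force oracle."""
import numpy as np
import pytest

from mammocalc.cluster import (
    count_clusters_per_woman,
    dbscan_group,
    shape_filter,
)
from mammocalc.types import ClusterSet

from conftest import make_spot


def brute_force_dbscan(points, eps, min_pts):
    """Textbook DBSCAN by direct neighborhood enumeration.

    Clusters are expanded one at a time in index-scan order, so border points
    join the first cluster that reaches them — the same convention as the
    production path.
    """
    n = len(points)
    pts = np.asarray(points, dtype=float)
    neighbors = [
        [j for j in range(n) if np.hypot(*(pts[i] - pts[j])) <= eps] for i in range(n)
    ]
    core = [len(nb) >= min_pts for nb in neighbors]
    labels = [None] * n
    cid = 0
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            j = queue.pop(0)
            if core[j]:
                for k in neighbors[j]:
                    if labels[k] is None:
                        labels[k] = cid
                        queue.append(k)
        cid += 1
    return [-1 if lab is None else lab for lab in labels]


def _partition(labels):
    clusters = {}
    noise = set()
    for i, lab in enumerate(labels):
        if lab == -1:
            noise.add(i)
        else:
            clusters.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in clusters.values()}, noise


class TestShapeFilter:
    def test_empty_input(self):
        survivors, removed = shape_filter([])
        assert survivors == [] and sum(removed.values()) == 0

    def test_single_pixel_dust_removed(self):
        spots = [make_spot(10, 10, area=1), make_spot(20, 20, area=4)]
        survivors, removed = shape_filter(spots, min_area_px=2)
        assert len(survivors) == 1 and removed["area"] == 1

    def test_oversized_component_removed(self):
        spots = [make_spot(10, 10, area=500)]
        survivors, removed = shape_filter(spots, max_area_px=80)
        assert survivors == [] and removed["area"] == 1

    def test_elongated_fragment_removed_round_specks_kept(self):
        spots = [make_spot(5 * i, 5, ecc=0.2) for i in range(8)]
        spots.append(make_spot(50, 50, ecc=0.99))
        survivors, removed = shape_filter(spots, max_eccentricity=0.95)
        assert len(survivors) == 8 and removed["eccentricity"] == 1

    def test_ridge_riding_spot_vetoed(self):
        line_map = np.zeros((64, 64))
        line_map[30, :] = 0.9
        on_ridge = make_spot(30, 20, coords=[[30, 19], [30, 20], [30, 21]])
        off_ridge = make_spot(10, 10, coords=[[10, 10], [10, 11]])
        survivors, removed = shape_filter(
            [on_ridge, off_ridge], line_map=line_map, line_veto=0.5
        )
        assert survivors == [off_ridge] and removed["line"] == 1

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            shape_filter([], min_area_px=10, max_area_px=2)


class TestDbscanGroup:
    def test_triangle_forms_single_cluster(self):
        spots = [make_spot(0, 0), make_spot(0, 40), make_spot(40, 0)]  # 2 mm apart
        cs = dbscan_group(spots, eps_mm=5.0, min_pts=3, spacing_mm=0.05)
        assert cs.n_clusters == 1
        assert cs.n_isolated_discarded == 0
        assert sorted(cs.clusters[0].member_indices) == [0, 1, 2]

    def test_two_distant_spots_are_noise(self):
        spots = [make_spot(0, 0), make_spot(400, 400)]
        cs = dbscan_group(spots, eps_mm=5.0, min_pts=3, spacing_mm=0.05)
        assert cs.n_clusters == 0 and cs.n_isolated_discarded == 2

    def test_matches_brute_force_oracle_on_random_configurations(self):
        rng = np.random.default_rng(42)
        for trial in range(40):
            n = int(rng.integers(1, 13))
            pts = rng.uniform(0, 20, (n, 2))  # mm
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            pts = pts[order]  # same scan order for both paths
            spots = [make_spot(r / 0.05, c / 0.05) for r, c in pts]
            cs = dbscan_group(spots, eps_mm=5.0, min_pts=3, spacing_mm=0.05)
            got_labels = np.full(n, -1)
            for j, cl in enumerate(cs.clusters):
                got_labels[cl.member_indices] = j
            want = brute_force_dbscan(pts, eps=5.0, min_pts=3)
            assert _partition(got_labels) == _partition(want), f"trial {trial}"

    def test_partition_invariant_under_permutation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 15, (30, 2))
        spots = [make_spot(r / 0.05, c / 0.05) for r, c in pts]

        def canonical(cs):
            return {
                frozenset(tuple(np.round(pts[i], 9)) for i in cl.member_indices)
                for cl in cs.clusters
            }

        base = canonical(dbscan_group(spots, 5.0, 3, 0.05))
        for _ in range(5):
            perm = rng.permutation(len(spots))
            shuffled = [spots[i] for i in perm]
            cs = dbscan_group(shuffled, 5.0, 3, 0.05)
            got = {
                frozenset(tuple(np.round(pts[perm[i]], 9)) for i in cl.member_indices)
                for cl in cs.clusters
            }
            assert got == base

    def test_cluster_count_non_increasing_in_min_pts(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 25, (40, 2))
        spots = [make_spot(r / 0.05, c / 0.05) for r, c in pts]
        counts = [dbscan_group(spots, 5.0, m, 0.05).n_clusters for m in (2, 3, 4, 5, 6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_hull_area_of_square_cluster(self):
        # 2 mm x 2 mm square of four spots
        spots = [make_spot(0, 0), make_spot(0, 40), make_spot(40, 0), make_spot(40, 40)]
        cs = dbscan_group(spots, eps_mm=5.0, min_pts=3, spacing_mm=0.05)
        assert cs.n_clusters == 1
        assert cs.clusters[0].hull_area_mm2 == pytest.approx(4.0, rel=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            dbscan_group([], eps_mm=0.0)
        with pytest.raises(ValueError):
            dbscan_group([], min_pts=1)


class TestPerWomanCount:
    @pytest.mark.parametrize("nl,nr,total", [(0, 0, 0), (2, 1, 3)])
    def test_sum_over_sides(self, nl, nr, total):
        def cs(n):
            spots3 = [make_spot(0, 0), make_spot(0, 20), make_spot(20, 0)]
            base = dbscan_group(spots3, 5.0, 3, 0.05)
            return ClusterSet(clusters=base.clusters * n)

        assert count_clusters_per_woman(cs(nl), cs(nr)) == total

    def test_missing_side_is_an_error(self):
        with pytest.raises(ValueError, match="missing side"):
            count_clusters_per_woman(None, ClusterSet(clusters=[]))


def test_noise_candidates_removed_by_cleaning_chain():
    """Pure-noise phantoms: the cleaning chain (shape filter + isolation
    discard) removes at least half of raw candidates, and yields almost no
    clusters."""
    from mammocalc.config import RunConfig
    from mammocalc.pipeline import detect_clusters
    from mammocalc.synthetic import random_phantom

    cfg = RunConfig()
    raw, kept, clusters = [], [], []
    for seed in range(20):
        img, _ = random_phantom(seed=400 + seed, n_clusters=0, shape_px=(512, 384))
        res = detect_clusters(img, cfg)
        raw.append(res.n_candidates)
        kept.append(sum(len(c.member_indices) for c in res.cluster_set.clusters))
        clusters.append(res.n_clusters)
    assert np.median(kept) <= 0.5 * np.median(raw)
    assert np.mean(clusters) <= 1.0
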