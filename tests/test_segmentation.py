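"""Elevation filter, k-NN graph, PCA features and region growing."""

import collections

import numpy as np
import pytest

from podsplit3d import (
    GrowthParams,
    PointCloud,
    build_neighbor_graph,
    elevation_filter,
    estimate_normals_curvature,
    region_growing,
)
from podsplit3d.synthetic import PodSpec, adherent_pod_cloud


# ---------------------------------------------------------------------------
# naive re-implementation used as the independent oracle (no spatial tree)
# ---------------------------------------------------------------------------

def naive_knn(points, k):
    n = len(points)
    kk = min(k, n - 1)
    out = np.empty((n, kk), dtype=int)
    for i in range(n):
        d = np.linalg.norm(points - points[i], axis=1)
        idx = [j for j in range(n) if j != i]
        idx.sort(key=lambda j: (d[j], j))
        out[i] = idx[:kk]
    return out


def naive_region_growing(points, normals, curv, nbr, params):
    n = len(points)
    cos_t = np.cos(np.radians(params.angle_thresh))
    labels = np.full(n, -1, dtype=int)
    unassigned = np.ones(n, dtype=bool)
    seed_order = sorted(range(n), key=lambda i: (curv[i], i))
    ptr = 0
    regions = []
    while unassigned.sum() >= params.min_region:
        while ptr < n and not unassigned[seed_order[ptr]]:
            ptr += 1
        if ptr >= n:
            break
        s0 = seed_order[ptr]
        member = [s0]
        unassigned[s0] = False
        queue = [s0]
        while queue:
            s = queue.pop(0)
            for j in nbr[s]:
                if not unassigned[j]:
                    continue
                if abs(normals[j] @ normals[s]) >= cos_t:
                    unassigned[j] = False
                    member.append(j)
                    if curv[j] < params.curv_thresh:
                        queue.append(j)
        if len(member) >= params.min_region:
            regions.append(member)
    for rid, member in enumerate(regions):
        labels[member] = rid
    return labels


# ---------------------------------------------------------------------------
# elevation filter
# ---------------------------------------------------------------------------

class TestElevationFilter:
    def test_window_selects_exact_band(self):
        cloud = PointCloud(points=[[0, 0, 0], [0, 0, 5], [0, 0, 10]])
        out = elevation_filter(cloud, 1.0, 9.0)
        assert len(out) == 1 and out.points[0, 2] == 5.0

    def test_full_window_is_identity(self, rng):
        cloud = PointCloud(points=rng.normal(size=(30, 3)))
        out = elevation_filter(cloud, -100.0, 100.0)
        assert np.array_equal(out.points, cloud.points)

    def test_empty_result_warns(self):
        cloud = PointCloud(points=[[0, 0, 0]])
        with pytest.warns(UserWarning):
            out = elevation_filter(cloud, 5.0, 6.0)
        assert len(out) == 0

    def test_pod_on_table_scene(self):
        pod = PodSpec("common", r1=6, r2=6, separation=5, waist=0.9,
                      bump_amp=0.0)
        cloud, _ = adherent_pod_cloud([pod], 2000, seed=1)
        table = PointCloud(points=np.column_stack([
            np.linspace(-20, 20, 500), np.zeros(500), np.zeros(500)]))
        both = PointCloud(points=np.vstack([table.points, cloud.points]))
        out = elevation_filter(both, 0.5, 100.0)
        kept_pod = (cloud.points[:, 2] >= 0.5).sum()
        assert len(out) == kept_pod  # table gone, pod band preserved


# ---------------------------------------------------------------------------
# neighbour graph
# ---------------------------------------------------------------------------

class TestNeighborGraph:
    def test_collinear_tie_breaks_to_lower_index(self):
        cloud = PointCloud(points=[[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        g = build_neighbor_graph(cloud, 1)
        assert g.neighbor_indices[1, 0] == 0  # both endpoints at distance 1

    def test_k_at_least_n_minus_1_lists_everyone(self):
        cloud = PointCloud(points=np.diag([1.0, 2.0, 3.0]))
        g = build_neighbor_graph(cloud, 10)
        for i in range(3):
            assert set(g.neighbor_indices[i]) == {0, 1, 2} - {i}

    def test_matches_bruteforce_oracle(self, rng):
        pts = rng.normal(size=(200, 3))
        cloud = PointCloud(points=pts)
        g = build_neighbor_graph(cloud, 10)
        assert np.array_equal(g.neighbor_indices, naive_knn(pts, 10))

    def test_invalid_k(self):
        cloud = PointCloud(points=np.zeros((5, 3)))
        with pytest.raises(ValueError):
            build_neighbor_graph(cloud, 0)


# ---------------------------------------------------------------------------
# normals and curvature
# ---------------------------------------------------------------------------

class TestFeatures:
    def test_coplanar_neighbourhood_is_flat(self, rng):
        xy = rng.normal(size=(40, 2))
        pts = np.column_stack([xy, xy @ [0.3, -0.2]])  # plane z = .3x - .2y
        cloud = PointCloud(points=pts)
        g = build_neighbor_graph(cloud, 12)
        out = estimate_normals_curvature(cloud, g)
        assert np.allclose(out.curvatures, 0.0, atol=1e-12)
        true_n = np.array([-0.3, 0.2, 1.0])
        true_n /= np.linalg.norm(true_n)
        dots = np.abs(out.normals @ true_n)
        assert np.all(dots > 1 - 1e-9)

    def test_isotropic_neighbourhood_has_maximal_curvature(self):
        # centre + octahedron: covariance is a multiple of the identity
        pts = np.vstack([np.zeros(3), np.eye(3), -np.eye(3)])
        cloud = PointCloud(points=pts)
        g = build_neighbor_graph(cloud, 6)
        out = estimate_normals_curvature(cloud, g)
        assert out.curvatures[0] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_sphere_cap_normals_are_radial(self, rng):
        R = 10.0
        n = 5000
        phi = rng.uniform(0, 2 * np.pi, n)
        theta = np.arccos(rng.uniform(np.cos(np.radians(30)), 1.0, n))
        pts = R * np.column_stack([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ])
        cloud = PointCloud(points=pts)
        g = build_neighbor_graph(cloud, 20)
        out = estimate_normals_curvature(cloud, g)
        radial = pts / R
        ang = np.degrees(np.arccos(np.clip(
            np.abs(np.einsum("ij,ij->i", out.normals, radial)), -1, 1)))
        assert ang.max() < 2.0

    def test_degenerate_neighbourhood_flagged(self):
        cloud = PointCloud(points=np.zeros((5, 3)))
        g = build_neighbor_graph(cloud, 4)
        with pytest.warns(UserWarning, match="zero spread"):
            out = estimate_normals_curvature(cloud, g)
        assert np.allclose(out.curvatures, 0.0)
        assert np.allclose(out.normals, [0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def _flat_patch(rng, n, offset):
    xy = rng.uniform(-5, 5, size=(n, 2))
    return np.column_stack([xy[:, 0] + offset[0], xy[:, 1] + offset[1],
                            np.full(n, offset[2])])


class TestRegionGrowing:
    def test_two_distant_patches_two_regions(self, rng):
        pts = np.vstack([_flat_patch(rng, 150, (0, 0, 0)),
                         _flat_patch(rng, 150, (1000, 0, 0))])
        cloud = PointCloud(points=pts)
        g = build_neighbor_graph(cloud, 8)
        cloud = estimate_normals_curvature(cloud, g)
        labeled, regions = region_growing(cloud, g, GrowthParams(k=8, min_region=50))
        assert len(regions) == 2
        assert (labeled.labels == -1).sum() == 0
        # a region never spans both patches
        assert len(set(labeled.labels[:150])) == 1
        assert len(set(labeled.labels[150:])) == 1

    def test_single_plane_single_region(self, rng):
        cloud = PointCloud(points=_flat_patch(rng, 300, (0, 0, 0)))
        g = build_neighbor_graph(cloud, 10)
        cloud = estimate_normals_curvature(cloud, g)
        labeled, regions = region_growing(cloud, g, GrowthParams(k=10, min_region=50))
        assert len(regions) == 1 and (labeled.labels == 0).all()

    def test_label_partition_and_min_region(self, rng):
        pods = [PodSpec("common", 6, 6, 5, 0.9, position=(-7, 0)),
                PodSpec("common", 6, 6, 5, 0.9, position=(7, 0))]
        cloud, _ = adherent_pod_cloud(pods, 3000, seed=2)
        g = build_neighbor_graph(cloud, 20)
        cloud = estimate_normals_curvature(cloud, g)
        params = GrowthParams(k=20, min_region=80)
        labeled, regions = region_growing(cloud, g, params)
        sizes = [r.size for r in regions]
        assert all(s >= params.min_region for s in sizes)
        assert sum(sizes) + (labeled.labels == -1).sum() == len(cloud)
        assert sorted({r.region_id for r in regions}) == list(range(len(regions)))

    def test_deterministic(self, rng):
        pods = [PodSpec("common", 6, 6, 5, 0.9)]
        cloud, _ = adherent_pod_cloud(pods, 2000, seed=3)
        g = build_neighbor_graph(cloud, 15)
        cloud = estimate_normals_curvature(cloud, g)
        l1, _ = region_growing(cloud, g, GrowthParams(k=15))
        l2, _ = region_growing(cloud, g, GrowthParams(k=15))
        assert np.array_equal(l1.labels, l2.labels)

    def test_widening_thresholds_never_adds_regions(self, rng):
        pods = [PodSpec("wasp_waist", 7, 7, 11, 0.5, position=(-9, 0)),
                PodSpec("common", 6, 6, 5, 0.9, position=(9, 0))]
        cloud, _ = adherent_pod_cloud(pods, 4000, seed=4)
        g = build_neighbor_graph(cloud, 20)
        cloud = estimate_normals_curvature(cloud, g)
        counts = []
        for ang, cv in [(8.0, 0.02), (15.0, 0.08), (30.0, 0.2)]:
            _, regions = region_growing(
                cloud, g, GrowthParams(k=20, angle_thresh=ang, curv_thresh=cv,
                                       min_region=100))
            counts.append(len(regions))
        assert counts == sorted(counts, reverse=True)

    def test_matches_naive_oracle(self, rng):
        pods = [PodSpec("common", 6, 6, 5, 0.9, position=(-7, 0)),
                PodSpec("common", 6, 6, 5, 0.9, position=(7, 0))]
        cloud, _ = adherent_pod_cloud(pods, 500, seed=5)
        params = GrowthParams(k=12, min_region=40)
        g = build_neighbor_graph(cloud, params.k)
        assert np.array_equal(g.neighbor_indices, naive_knn(cloud.points, params.k))
        cloud = estimate_normals_curvature(cloud, g)
        labeled, _ = region_growing(cloud, g, params)
        oracle = naive_region_growing(cloud.points, cloud.normals,
                                      cloud.curvatures, g.neighbor_indices,
                                      params)
        assert np.array_equal(labeled.labels, oracle)

    def test_missing_features_rejected(self, rng):
        cloud = PointCloud(points=rng.normal(size=(50, 3)))
        g = build_neighbor_graph(cloud, 5)
        with pytest.raises(ValueError, match="normals"):
            region_growing(cloud, g, GrowthParams(k=5))
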