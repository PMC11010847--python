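"""Voxel filter and K-means segmentation against independent oracles."""

import itertools

import numpy as np
import pytest

from pigback import (
    PointCloud, VoxelFilterParams, voxel_downsample,
    kmeans_cluster, elbow_select_k, extract_pig_cluster,
)
from pigback.synth import make_blob_scene


def brute_force_voxel(points, edge):
    """Reference binning: floor((p - min) / edge), mean per occupied cell."""
    origin = points.min(axis=0)
    cells = np.floor((points - origin) / edge).astype(int)
    out = {}
    for c, p in zip(map(tuple, cells), points):
        out.setdefault(c, []).append(p)
    return {c: np.mean(v, axis=0) for c, v in out.items()}


class TestVoxelDownsample:
    def test_single_voxel_mean(self):
        corners = np.array(list(itertools.product([0.0, 0.029], repeat=3)))
        out = voxel_downsample(PointCloud(corners), VoxelFilterParams(0.03))
        assert len(out) == 1
        np.testing.assert_allclose(out.points[0], corners.mean(axis=0))

    def test_single_point_identity(self):
        out = voxel_downsample(
            PointCloud(np.array([[0.5, -1.0, 2.0]])), VoxelFilterParams(0.03)
        )
        np.testing.assert_allclose(out.points, [[0.5, -1.0, 2.0]])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 1, size=(1000, 3))
            out = voxel_downsample(PointCloud(pts), VoxelFilterParams(0.25))
            ref = brute_force_voxel(pts, 0.25)
            assert len(out) == len(ref)
            got = {tuple(np.round(p, 9)) for p in out.points}
            want = {tuple(np.round(p, 9)) for p in ref.values()}
            assert got == want

    def test_conservation_and_containment(self, rng):
        pts = rng.normal(0, 1, size=(2000, 3))
        e = 0.2
        out = voxel_downsample(PointCloud(pts), VoxelFilterParams(e))
        origin = pts.min(axis=0)
        in_cells = np.floor((pts - origin) / e).astype(int)
        assert len(out) == len(np.unique(in_cells, axis=0))
        out_cells = np.floor((out.points - origin) / e).astype(int)
        # every output point lies inside an occupied cell
        occupied = {tuple(c) for c in in_cells}
        assert all(tuple(c) in occupied for c in out_cells)

    def test_monotone_in_edgelength(self, rng):
        pts = rng.uniform(0, 1, size=(3000, 3))
        sizes = [
            len(voxel_downsample(PointCloud(pts), VoxelFilterParams(e)))
            for e in (0.03, 0.04, 0.05)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_color_averaging(self):
        pts = np.array([[0.0, 0, 0], [0.01, 0, 0]])
        col = np.array([[100, 0, 0], [101, 0, 0]])
        out = voxel_downsample(PointCloud(pts, col), VoxelFilterParams(0.1))
        assert out.colors[0, 0] in (100, 101)  # rounded mean of 100.5

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            voxel_downsample(PointCloud(np.empty((0, 3))), VoxelFilterParams(0.03))
        with pytest.raises(ValueError):
            VoxelFilterParams(-0.1)


def exhaustive_best_sse(points, K):
    """Minimum SSE over every assignment of N points to at most K clusters.

    Uses SSE = sum|x|^2 - sum_k |sum_k|^2 / n_k, evaluated for all K^N label
    vectors at once.
    """
    n = len(points)
    grids = np.meshgrid(*([np.arange(K)] * n), indexing="ij")
    assignments = np.stack([g.ravel() for g in grids], axis=1)  # (K^n, n)
    total = (points ** 2).sum()
    reduction = np.zeros(len(assignments))
    for k in range(K):
        mask = (assignments == k).astype(float)          # (K^n, n)
        counts = mask.sum(axis=1)
        sums = mask @ points                              # (K^n, 3)
        nonzero = counts > 0
        reduction[nonzero] += (
            (sums[nonzero] ** 2).sum(axis=1) / counts[nonzero]
        )
    return float(total - reduction.max())


class TestKMeans:
    def test_k1_closed_form(self, rng):
        pts = rng.normal(size=(50, 3))
        seg = kmeans_cluster(PointCloud(pts), 1, seed=0)
        np.testing.assert_allclose(seg.centroids[0], pts.mean(axis=0))
        assert seg.sse == pytest.approx(((pts - pts.mean(0)) ** 2).sum())

    def test_two_separated_blobs(self, rng):
        a = rng.normal([0, 0, 0], 0.02, size=(200, 3))
        b = rng.normal([1, 0, 0], 0.02, size=(200, 3))
        seg = kmeans_cluster(PointCloud(np.vstack([a, b])), 2, seed=1)
        first, second = seg.labels[:200], seg.labels[200:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    @pytest.mark.parametrize("n,K", [(8, 2), (10, 3), (12, 3)])
    def test_attains_exhaustive_optimum(self, rng, n, K):
        pts = rng.uniform(0, 1, size=(n, 3))
        seg = kmeans_cluster(PointCloud(pts), K, seed=2, n_restarts=60)
        assert seg.sse == pytest.approx(exhaustive_best_sse(pts, K), rel=1e-9)

    def test_agrees_with_sklearn(self, rng):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        # well-separated blobs: both optimizers find the same optimum
        blobs = np.vstack([
            rng.normal(c, 0.05, size=(80, 3))
            for c in ([0, 0, 0], [2, 0, 0], [0, 2, 0])
        ])
        seg = kmeans_cluster(PointCloud(blobs), 3, seed=3)
        km = sklearn_cluster.KMeans(3, n_init=10, random_state=0).fit(blobs)
        assert seg.sse == pytest.approx(km.inertia_, rel=1e-6)
        # unstructured data: best-of-restarts is at least as good
        pts = rng.normal(size=(300, 3))
        seg = kmeans_cluster(PointCloud(pts), 3, seed=3)
        km = sklearn_cluster.KMeans(3, n_init=20, random_state=0).fit(pts)
        assert seg.sse <= km.inertia_ * (1 + 1e-9)

    def test_determinism(self, rng):
        pts = rng.normal(size=(100, 3))
        a = kmeans_cluster(PointCloud(pts), 3, seed=7)
        b = kmeans_cluster(PointCloud(pts), 3, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.sse == b.sse

    def test_parameter_errors(self, rng):
        cloud = PointCloud(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            kmeans_cluster(cloud, 6)
        with pytest.raises(ValueError):
            kmeans_cluster(cloud, 0)


class TestElbow:
    def test_four_blob_scene(self):
        cloud, _ = make_blob_scene(4, seed=0)
        k, sse = elbow_select_k(cloud, (1, 8), seed=0, n_restarts=10)
        assert k == 4
        assert np.all(np.diff(sse) <= 1e-6)  # SSE non-increasing in K

    def test_three_blob_scene(self):
        cloud, _ = make_blob_scene(3, seed=1)
        k, _ = elbow_select_k(cloud, (1, 6), seed=1, n_restarts=10)
        assert k == 3

    def test_translation_invariance(self):
        cloud, _ = make_blob_scene(4, seed=2)
        k1, _ = elbow_select_k(cloud, (1, 6), seed=3, n_restarts=10)
        shifted = PointCloud(cloud.points + np.array([5.0, -3.0, 2.0]))
        k2, _ = elbow_select_k(shifted, (1, 6), seed=3, n_restarts=10)
        assert k1 == k2 == 4

    def test_needs_three_candidates(self, rng):
        cloud = PointCloud(rng.normal(size=(50, 3)))
        with pytest.raises(ValueError):
            elbow_select_k(cloud, (2, 3), seed=0)


class TestExtractPigCluster:
    def test_two_layer_scene(self, rng):
        # layer separation (0.8 m) dominates each layer's footprint
        floor = np.column_stack([
            rng.uniform(-0.6, 0.6, 400), rng.uniform(-0.6, 0.6, 400),
            np.full(400, -2.5),
        ])
        slab = np.column_stack([
            rng.uniform(-0.5, 0.5, 200), rng.uniform(-0.2, 0.2, 200),
            np.full(200, -1.7),
        ])
        cloud = PointCloud(np.vstack([floor, slab]))
        seg = kmeans_cluster(cloud, 2, seed=0)
        pig = extract_pig_cluster(cloud, seg)
        assert len(pig) == 200
        assert pig.points[:, 2].mean() == pytest.approx(-1.7, abs=1e-6)

    def test_size_mismatch_rejected(self, rng):
        cloud = PointCloud(rng.normal(size=(30, 3)))
        seg = kmeans_cluster(cloud, 2, seed=0)
        with pytest.raises(ValueError):
            extract_pig_cluster(PointCloud(rng.normal(size=(10, 3))), seg)
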