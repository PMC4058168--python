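"""Texture features, clustering, and wall selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import cartwave as cw
from cartwave.exceptions import NoWallFoundError
from cartwave.phantom import PhantomConfig, generate_phantom
from cartwave.segmentation import (
    compute_spatial_features,
    compute_temporal_std,
    kmeans_segment,
    select_wall,
)


class TestSpatialFeatures:
    def test_constant_frame_has_no_variation(self):
        f = compute_spatial_features(np.full((32, 32), 0.5), window=9)
        np.testing.assert_allclose(f[..., 0], 0.5, atol=1e-12)
        np.testing.assert_allclose(f[..., 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(f[..., 2], 0.0, atol=1e-12)

    def test_checkerboard_interior_matches_direct_window_count(self):
        frame = np.indices((32, 32)).sum(axis=0) % 2
        frame = frame.astype(float)
        f = compute_spatial_features(frame, window=9)
        r, c = 15, 16
        win = frame[r - 4 : r + 5, c - 4 : c + 5]
        ones = win.sum()
        assert f[r, c, 0] == pytest.approx(ones / 81, abs=1e-9)
        p1, p0 = ones / 81, 1 - ones / 81
        expect_entropy = -(p1 * np.log2(p1) + p0 * np.log2(p0))
        assert f[r, c, 2] == pytest.approx(expect_entropy, abs=1e-6)
        assert f[r, c, 2] == pytest.approx(1.0, abs=1e-3)

    def test_isolated_bright_pixel_raises_std_only_nearby(self):
        frame = np.zeros((21, 21))
        frame[10, 10] = 1.0
        f = compute_spatial_features(frame, window=9)
        rr, cc = np.nonzero(f[..., 1] > 0)
        assert np.all(np.abs(rr - 10) <= 4) and np.all(np.abs(cc - 10) <= 4)
        assert f[10, 10, 1] > 0

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            compute_spatial_features(np.zeros((8, 8)), window=8)
        with pytest.raises(ValueError):
            compute_spatial_features(np.zeros((8, 8)), window=1)

    def test_entropy_invariant_under_bin_relabeling(self):
        rng = np.random.default_rng(0)
        centers = (np.arange(16) + 0.5) / 16
        frame = centers[rng.integers(0, 16, size=(24, 24))]
        perm = rng.permutation(16)
        relabeled = centers[perm][np.searchsorted(centers, frame)]
        e1 = compute_spatial_features(frame, 5)[..., 2]
        e2 = compute_spatial_features(relabeled, 5)[..., 2]
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_mean_channel_linear_in_intensity_scale(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 1, (16, 16))
        m1 = compute_spatial_features(frame, 5)[..., 0]
        m2 = compute_spatial_features(0.5 * frame, 5)[..., 0]
        np.testing.assert_allclose(m2, 0.5 * m1, atol=1e-12)


class TestTemporalStd:
    def test_static_sequence_is_zero(self):
        frames = np.broadcast_to(np.random.default_rng(0).uniform(size=(8, 8)), (10, 8, 8))
        np.testing.assert_allclose(compute_temporal_std(frames.copy()), 0.0, atol=1e-12)

    def test_alternating_binary_pixel_gives_half(self):
        frames = np.zeros((10, 4, 4))
        frames[::2, 1, 1] = 1.0
        assert compute_temporal_std(frames)[1, 1] == pytest.approx(0.5)

    def test_three_level_pixel_population_std(self):
        frames = np.zeros((3, 2, 2))
        frames[:, 0, 0] = [0.0, 0.5, 1.0]
        assert compute_temporal_std(frames)[0, 0] == pytest.approx(np.sqrt(1 / 6))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_temporal_std(np.zeros((1, 4, 4)))


class TestKMeans:
    def test_k1_is_a_single_label(self):
        rng = np.random.default_rng(0)
        lab = kmeans_segment(rng.uniform(size=(10, 10, 4)), k=1)
        assert np.all(lab == 0)

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 3, size=(30, 30))
        centers = np.array([[0, 0, 0, 0], [10, 10, 0, 0], [0, 0, 10, 10]], dtype=float)
        feats = centers[truth] + 0.1 * rng.standard_normal((30, 30, 4))
        lab = kmeans_segment(feats, k=3, seed=0)
        assert adjusted_rand_score(truth.ravel(), lab.ravel()) == pytest.approx(1.0)

    def test_partition_invariant_to_per_channel_affine_rescale(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 3, size=(20, 20))
        centers = np.array([[0, 0, 0, 0], [8, 8, 0, 0], [0, 0, 8, 8]], dtype=float)
        feats = centers[truth] + 0.1 * rng.standard_normal((20, 20, 4))
        scaled = feats * np.array([3.0, 0.2, 11.0, 1e3]) + np.array([5, -2, 0, 40.0])
        a = kmeans_segment(feats, k=3, seed=1)
        b = kmeans_segment(scaled, k=3, seed=1)
        assert adjusted_rand_score(a.ravel(), b.ravel()) == pytest.approx(1.0)

    def test_too_few_distinct_vectors_rejected(self):
        with pytest.raises(ValueError):
            kmeans_segment(np.zeros((5, 5, 4)), k=3)

    def test_phantom_regions_land_in_distinct_clusters(self):
        cfg = PhantomConfig(seed=1)
        seq, _, truth = generate_phantom(cfg)
        seg = cw.segment_sequence(seq, seed=1)
        rows = np.arange(cfg.height)[:, None] + 0.5
        mb = truth.boundary.mean(axis=0)[None, :]
        regions = {
            "lumen": rows < mb - 2,
            "wall": truth.wall_mask,
            "tissue": rows > mb + cfg.wall_thickness + 2,
        }
        modes = {}
        for name, reg in regions.items():
            vals, counts = np.unique(seg.labels[reg], return_counts=True)
            assert counts.max() / counts.sum() >= 0.9, name
            modes[name] = vals[counts.argmax()]
        assert len(set(modes.values())) == 3


class TestSelectWall:
    def test_moving_visible_cluster_wins(self):
        labels = np.zeros((10, 20), dtype=int)
        labels[4:7] = 1
        tstd = np.where(labels == 1, 0.3, 0.0)
        intensity = np.where(labels == 1, 0.9, 0.1)
        mask = select_wall(labels, tstd, intensity)
        assert np.array_equal(mask, labels == 1)

    def test_static_scene_raises_no_wall(self):
        labels = np.zeros((10, 20), dtype=int)
        labels[4:7] = 1
        tstd = np.zeros_like(labels, dtype=float)
        intensity = np.where(labels == 1, 0.9, 0.1)
        with pytest.raises(NoWallFoundError):
            select_wall(labels, tstd, intensity)

    def test_invisible_mover_fails_visibility_guard(self):
        labels = np.zeros((10, 20), dtype=int)
        labels[4:7] = 1
        tstd = np.where(labels == 1, 0.3, 0.0)
        intensity = np.where(labels == 1, 0.05, 0.9)  # mover is dark
        with pytest.raises(NoWallFoundError):
            select_wall(labels, tstd, intensity)

    def test_output_is_single_4connected_component(self, young_cases):
        from skimage.measure import label as cc_label

        for case in young_cases[:3]:
            cfg = case.config
            seq, _, _ = generate_phantom(cfg)
            seg = cw.segment_sequence(seq, seed=cfg.seed)
            assert cc_label(seg.wall_mask, connectivity=1).max() == 1
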