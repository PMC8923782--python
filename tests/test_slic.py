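"""SLIC superpixels: seed grid, perturbation, assignment, iteration."""

import numpy as np
import pytest

from spurnet.io_formats import RgbImage
from spurnet.slic import (
    SlicParams,
    assign_pixels,
    init_seeds,
    perturb_seeds,
    slic,
    update_seeds,
)


def brute_force_assign(features, seeds, S, m):
    """Oracle: all-pairs nearest-seed assignment, explicit loops over seeds."""
    h, w = features.shape[:2]
    best = np.full((h, w), np.inf)
    labels = np.zeros((h, w), dtype=np.int32)
    for sid, seed in enumerate(seeds):
        dc2 = ((features - seed.color) ** 2).sum(axis=2)
        rr = np.arange(h)[:, None] - seed.position[0]
        cc = np.arange(w)[None, :] - seed.position[1]
        d2 = dc2 / (m * m) + (rr**2 + cc**2) / (S * S)
        better = d2 < best
        best[better] = d2[better]
        labels[better] = sid
    return labels


class TestInitSeeds:
    def test_exact_square_grid(self):
        S, seeds = init_seeds(256, 64)
        assert S == 32.0 and len(seeds) == 64

    def test_small_grid_positions_by_hand(self):
        S, seeds = init_seeds(6, 4)
        assert S == 3.0
        assert [s.position for s in seeds] == [(1.0, 1.0), (1.0, 4.0), (4.0, 1.0), (4.0, 4.0)]

    def test_realized_count_may_differ_from_request(self):
        S, seeds = init_seeds(256, 50)
        assert S == pytest.approx(np.sqrt(65536 / 50))
        assert len(seeds) == 49  # spacing 36 -> 7x7 grid

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            init_seeds(4, 17)
        with pytest.raises(ValueError):
            init_seeds(1, 1)


class TestPerturbSeeds:
    def test_constant_image_keeps_positions(self):
        feats = np.full((16, 16, 3), 5.0)
        _, seeds = init_seeds(16, 4, feats)
        moved = perturb_seeds(feats, seeds)
        assert [s.position for s in moved] == [s.position for s in seeds]

    def test_seed_moves_to_unique_gradient_minimum_east(self):
        # V-shaped ramps give zero central difference only at (8, 9): the
        # unique gradient minimum one column east of the seed at (8, 8)
        rows = np.arange(17)[:, None].astype(float)
        cols = np.arange(17)[None, :].astype(float)
        feats = np.repeat((np.abs(cols - 9) + 0.1 * np.abs(rows - 8))[..., None], 3, axis=2)
        from spurnet.slic import SeedPoint

        seed = SeedPoint((8.0, 8.0), feats[8, 8].astype(float))
        moved = perturb_seeds(feats, [seed])[0]
        assert moved.position == (8.0, 9.0)

    def test_positions_match_exhaustive_window_scan(self, rng):
        feats = rng.normal(size=(32, 32, 3))
        _, seeds = init_seeds(32, 16, feats)
        moved = perturb_seeds(feats, seeds)
        from spurnet.slic import _gradient_map

        grad = _gradient_map(feats)
        for before, after in zip(seeds, moved):
            r0, c0 = int(before.position[0]), int(before.position[1])
            window = grad[max(0, r0 - 1) : r0 + 2, max(0, c0 - 1) : c0 + 2]
            r1, c1 = int(after.position[0]), int(after.position[1])
            assert grad[r1, c1] == window.min()
            assert abs(r1 - r0) <= 1 and abs(c1 - c0) <= 1

    def test_even_window_rejected(self, rng):
        feats = rng.normal(size=(8, 8, 3))
        _, seeds = init_seeds(8, 4, feats)
        with pytest.raises(ValueError):
            perturb_seeds(feats, seeds, n=4)


class TestAssignPixels:
    def test_identical_colors_reduce_to_spatial_nearest(self):
        feats = np.zeros((12, 12, 3))
        from spurnet.slic import SeedPoint

        seeds = [SeedPoint((3.0, 3.0), np.zeros(3)), SeedPoint((9.0, 9.0), np.zeros(3))]
        lab = assign_pixels(feats, seeds, S=8.0, m=10.0)
        assert lab.labels[2, 2] == 0 and lab.labels[10, 10] == 1

    def test_large_m_approaches_voronoi(self, rng):
        # side 15 gives a seed grid with no pixel equidistant to its two
        # nearest seeds, so the spatial argmin is unambiguous
        feats = rng.normal(size=(15, 15, 3))
        S, seeds = init_seeds(15, 4, feats)
        lab = assign_pixels(feats, seeds, S, m=1e9)
        d2 = np.stack(
            [
                (np.arange(15)[:, None] - s.position[0]) ** 2
                + (np.arange(15)[None, :] - s.position[1]) ** 2
                for s in seeds
            ]
        )
        order = np.sort(d2, axis=0)
        assert (order[0] < order[1]).all()  # unique nearest seed everywhere
        np.testing.assert_array_equal(lab.labels, np.argmin(d2, axis=0))

    def test_windowed_equals_brute_force_when_covered(self, rng):
        for K in (4, 9, 16):
            feats = rng.normal(size=(24, 24, 3))
            S, seeds = init_seeds(24, K, feats)
            lab = assign_pixels(feats, seeds, S, m=10.0)
            oracle = brute_force_assign(feats, seeds, S, m=10.0)
            np.testing.assert_array_equal(lab.labels, oracle)


class TestUpdateSeeds:
    def test_fixed_point_at_cluster_means(self):
        feats = np.zeros((8, 8, 3))
        from spurnet.slic import SeedPoint

        # two blocks: left half label 0, right half label 1
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[:, 4:] = 1
        from spurnet.slic import SuperpixelLabeling

        labeling = SuperpixelLabeling(lab, 2)
        seeds = [SeedPoint((3.5, 1.5), np.zeros(3)), SeedPoint((3.5, 5.5), np.zeros(3))]
        moved = update_seeds(labeling, feats, seeds)
        assert moved[0].position == (3.5, 1.5)
        assert moved[1].position == (3.5, 5.5)

    def test_centroid_arithmetic_and_bounds(self, rng):
        feats = rng.normal(size=(10, 10, 3))
        lab = (np.arange(100).reshape(10, 10) // 50).astype(np.int32)
        from spurnet.slic import SeedPoint, SuperpixelLabeling

        labeling = SuperpixelLabeling(lab, 2)
        seeds = [SeedPoint((0.0, 0.0), np.zeros(3))] * 2
        moved = update_seeds(labeling, feats, seeds)
        rows, cols = np.nonzero(lab == 0)
        assert moved[0].position == (rows.mean(), cols.mean())
        np.testing.assert_allclose(moved[0].color, feats[lab == 0].mean(axis=0))
        for s in moved:
            assert 0 <= s.position[0] <= 9 and 0 <= s.position[1] <= 9

    def test_empty_block_keeps_previous_seed(self):
        from spurnet.slic import SeedPoint, SuperpixelLabeling

        lab = np.zeros((4, 4), dtype=np.int32)
        labeling = SuperpixelLabeling(lab, 2)  # block 1 empty
        seeds = [SeedPoint((1.0, 1.0), np.zeros(3)), SeedPoint((2.0, 2.0), np.ones(3))]
        moved = update_seeds(labeling, np.zeros((4, 4, 3)), seeds)
        assert moved[1] is seeds[1]


class TestFullSlic:
    def test_constant_image_yields_regular_blocks(self):
        img = RgbImage(np.full((64, 64, 3), 128, dtype=np.uint8))
        lab = slic(img, SlicParams(K=16))
        sizes = lab.block_sizes()
        assert lab.n_blocks == 16
        assert sizes.sum() == 64 * 64
        assert sizes.min() > 0.75 * 256 and sizes.max() < 1.35 * 256

    def test_partition_and_determinism(self, small_scene):
        img, _ = small_scene
        lab1 = slic(img, SlicParams(K=16))
        lab2 = slic(img, SlicParams(K=16))
        np.testing.assert_array_equal(lab1.labels, lab2.labels)
        assert set(np.unique(lab1.labels)) == set(range(lab1.n_blocks))

    def test_blocks_are_connected_components(self, small_scene):
        from skimage.measure import label as cc_label

        img, _ = small_scene
        lab = slic(img, SlicParams(K=25))
        comp = cc_label(lab.labels, connectivity=1, background=-1)
        assert comp.max() == lab.n_blocks

    def test_two_flat_halves_split_along_color_boundary(self):
        px = np.zeros((32, 32, 3), dtype=np.uint8)
        px[:, 16:] = 220
        img = RgbImage(px)
        lab = slic(img, SlicParams(K=4, m=2.0))
        # every block must be color-pure: the block boundary coincides with
        # the color boundary (2-means on (color, position) would do the same)
        for b in range(lab.n_blocks):
            vals = px[..., 0][lab.labels == b]
            assert vals.min() == vals.max()

    def test_block_index_partitions_pixels(self, small_scene):
        img, _ = small_scene
        lab = slic(img, SlicParams(K=9))
        index = lab.block_index()
        counted = sum(len(rows) for rows, _ in index.values())
        assert counted == 64 * 64
        for b, (rows, cols) in index.items():
            assert (lab.labels[rows, cols] == b).all()

    def test_non_square_rejected(self):
        img = RgbImage(np.zeros((32, 48, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            slic(img, SlicParams(K=4))

    def test_rgb_color_space_ablation_runs(self, small_scene):
        img, _ = small_scene
        lab = slic(img, SlicParams(K=9, color_space="rgb"))
        assert lab.n_blocks >= 1
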