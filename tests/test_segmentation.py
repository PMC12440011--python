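"""Unit and property tests for the intact/detached segmentation core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import flood_fill_label
from organoidquant import (
    ImageSet,
    MultiChannelImage,
    SegmentationParams,
    above_background_mask,
    classify_intact_detached,
    estimate_background,
    live_dead_ratio,
    quantify_channel,
    segment_components,
    z_project,
)
from organoidquant.synthetic import ImageSpec, make_organoid_image


def _img(grid, channel="PODXL"):
    base = {ch: np.zeros_like(np.asarray(grid, dtype=float)) for ch in ("ECAD", "LTL", "PODXL")}
    base[channel] = np.asarray(grid, dtype=float)
    return MultiChannelImage(channels=base)


class TestEstimateBackground:
    def test_mean_of_per_image_minima(self):
        imgs = [_img(np.full((4, 4), v)) for v in (10.0, 20.0, 30.0)]
        assert estimate_background(imgs, "PODXL") == pytest.approx(20.0)

    def test_all_zero_images(self):
        imgs = [_img(np.zeros((4, 4)))] * 3
        assert estimate_background(imgs, "PODXL") == 0.0

    def test_matches_min_then_mean_oracle_on_random_images(self, rng):
        grids = [rng.uniform(0, 100, size=(16, 16)) for _ in range(50)]
        imgs = [_img(g) for g in grids]
        expected = float(np.mean([g.min() for g in grids]))
        assert estimate_background(imgs, "PODXL") == pytest.approx(expected, abs=1e-12)

    def test_missing_channel_names_image_and_channel(self):
        imgs = [_img(np.zeros((4, 4)))]
        with pytest.raises(KeyError, match="image 0.*'nuclei'"):
            estimate_background(imgs, "nuclei")

    def test_image_set_container(self):
        imgs = [_img(np.full((4, 4), v)) for v in (1.0, 3.0)]
        iset = ImageSet(images=imgs, conditions=["a", "b"], control_condition="a")
        assert estimate_background(iset, "PODXL") == pytest.approx(2.0)


class TestZProject:
    def test_max_of_two_slices(self):
        assert z_project(np.array([[[1.0]], [[5.0]]]))[0, 0] == 5.0

    def test_single_slice_identity(self):
        stack = np.arange(4.0).reshape(1, 2, 2)
        assert np.array_equal(z_project(stack), stack[0])

    def test_random_stack_matches_elementwise_loop(self, rng):
        stack = rng.uniform(0, 10, size=(5, 16, 16))
        expected = np.empty((16, 16))
        for y in range(16):
            for x in range(16):
                expected[y, x] = max(stack[z, y, x] for z in range(5))
        assert np.array_equal(z_project(stack, "max"), expected)

    @pytest.mark.parametrize("method", ["mean", "sum"])
    def test_alternative_projections(self, method, rng):
        stack = rng.uniform(0, 10, size=(3, 8, 8))
        expected = getattr(np, method)(stack, axis=0)
        assert np.allclose(z_project(stack, method), expected)

    def test_2d_input_passthrough(self):
        grid = np.ones((3, 3))
        assert z_project(grid) is grid


class TestAboveBackgroundMask:
    def test_constant_background_grid_is_empty(self):
        params = SegmentationParams(threshold_offset=5)
        grid = np.full((8, 8), 10.0)
        assert not above_background_mask(grid, 10.0, params).any()

    def test_bright_square_fully_kept(self):
        params = SegmentationParams(threshold_offset=5)
        grid = np.zeros((10, 10))
        grid[2:5, 2:5] = 20.0
        assert above_background_mask(grid, 10.0, params).sum() == 9

    def test_matches_pixelwise_plus_size_filter_oracle(self, rng):
        params = SegmentationParams(threshold_offset=10, min_object_px=4)
        grid = rng.uniform(0, 40, size=(32, 32))
        got = above_background_mask(grid, 10.0, params)
        raw = grid > 20.0
        lab = flood_fill_label(raw, 8)
        sizes = np.bincount(lab.ravel())
        expected = raw & np.isin(lab, [i for i in range(1, lab.max() + 1) if sizes[i] >= 4])
        assert np.array_equal(got, expected)

    def test_threshold_scale_invariance(self):
        """Scaling image+background+offset jointly leaves masks unchanged."""
        rng = np.random.default_rng(5)
        grid = rng.uniform(0, 50, size=(24, 24))
        for c in (0.5, 3.0, 17.0):
            p1 = SegmentationParams(threshold_offset=12.0)
            pc = SegmentationParams(threshold_offset=12.0 * c)
            m1 = above_background_mask(grid, 7.0, p1)
            mc = above_background_mask(grid * c, 7.0 * c, pc)
            assert np.array_equal(m1, mc)


class TestSegmentComponents:
    def test_single_blob_one_label(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        assert segment_components(mask).max() == 1

    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert segment_components(mask, 4).max() == 2
        assert segment_components(mask, 8).max() == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        for _ in range(100):
            mask = rng.random((32, 32)) < 0.4
            assert np.array_equal(
                segment_components(mask, connectivity),
                flood_fill_label(mask, connectivity),
            )


class TestClassifyIntactDetached:
    def _labels(self, *blobs, shape=(64, 64)):
        mask = np.zeros(shape, dtype=bool)
        for (y, x, h, w) in blobs:
            mask[y : y + h, x : x + w] = True
        return segment_components(mask)

    def test_single_large_component_is_intact(self):
        labels = self._labels((5, 5, 20, 20))
        params = SegmentationParams(main_body_min_px=50)
        intact, detached = classify_intact_detached(labels, params)
        assert intact == [1] and detached == []

    def test_body_plus_small_clusters(self):
        labels = self._labels((5, 5, 20, 20), (40, 40, 2, 3), (50, 10, 1, 5))
        params = SegmentationParams(main_body_min_px=50)
        intact, detached = classify_intact_detached(labels, params)
        areas = np.bincount(labels.ravel())
        assert sum(areas[i] for i in intact) == 400
        assert sum(areas[i] for i in detached) == 11

    def test_two_bodies_both_intact(self):
        labels = self._labels((2, 2, 20, 20), (30, 30, 20, 20), (55, 5, 2, 2))
        params = SegmentationParams(main_body_min_px=50)
        intact, detached = classify_intact_detached(labels, params)
        assert len(intact) == 2 and len(detached) == 1

    def test_no_body_falls_back_to_largest(self):
        labels = self._labels((2, 2, 3, 3), (10, 10, 4, 4))
        params = SegmentationParams(main_body_min_px=500, min_object_px=1)
        intact, _ = classify_intact_detached(labels, params)
        areas = np.bincount(labels.ravel())
        assert [areas[i] for i in intact] == [16]

    def test_empty_label_map_raises(self):
        with pytest.raises(ValueError, match="no above-background signal"):
            classify_intact_detached(np.zeros((8, 8), dtype=int), SegmentationParams())


class TestQuantifyChannel:
    def test_ratio_floored_when_no_detached(self):
        grid = np.zeros((32, 32))
        grid[5:20, 5:20] = 100.0
        img = _img(grid)
        q = quantify_channel(img, "PODXL", 0.0, SegmentationParams(threshold_offset=50))
        assert q.intact_area_px == 225
        assert q.detached_area_px == 0
        assert q.ratio_floored
        assert q.intact_detached_ratio == pytest.approx(225.0)

    def test_normalized_intensity_against_control(self):
        grid = np.zeros((32, 32))
        grid[5:20, 5:20] = 100.0
        img = _img(grid)
        q = quantify_channel(
            img, "PODXL", 0.0, SegmentationParams(threshold_offset=50), control_mean=100.0
        )
        assert q.normalized_intensity == pytest.approx(1.0)

    def test_nonpositive_control_mean_raises(self):
        grid = np.zeros((16, 16))
        grid[2:10, 2:10] = 100.0
        with pytest.raises(ValueError, match="control"):
            quantify_channel(
                _img(grid), "PODXL", 0.0, SegmentationParams(threshold_offset=50), control_mean=0.0
            )

    def test_area_conservation_on_synthetic_images(self, seg_params):
        """intact + detached equals total surviving above-threshold area."""
        for seed in range(5):
            img, _ = make_organoid_image(ImageSpec(seed=seed))
            bg = estimate_background([img], "PODXL")
            q = quantify_channel(img, "PODXL", bg, seg_params)
            total = above_background_mask(
                img.channels["PODXL"], bg, seg_params
            ).sum()
            assert q.intact_area_px + q.detached_area_px == total

    def test_recovers_true_intact_fraction(self, seg_params):
        img, truth = make_organoid_image(ImageSpec(seed=3))
        bg = estimate_background([img], "PODXL")
        q = quantify_channel(img, "PODXL", bg, seg_params)
        assert abs(q.intact_fraction - truth.intact_fraction["PODXL"]) <= 0.05

    def test_adding_detached_cell_decreases_ratio_only(self, seg_params):
        """One more isolated object: intact area unchanged, ratio strictly down."""
        spec0 = ImageSpec(seed=9, noise_sd=0.0, detached_cell_count=3)
        spec1 = ImageSpec(seed=9, noise_sd=0.0, detached_cell_count=4)
        img0, _ = make_organoid_image(spec0)
        img1, _ = make_organoid_image(spec1)
        q0 = quantify_channel(img0, "PODXL", 20.0, seg_params)
        q1 = quantify_channel(img1, "PODXL", 20.0, seg_params)
        assert q1.intact_area_px == q0.intact_area_px
        assert q1.intact_detached_ratio < q0.intact_detached_ratio

    def test_z_stack_is_projected_before_thresholding(self, seg_params):
        img, truth = make_organoid_image(ImageSpec(seed=4, z_slices=5))
        bg = estimate_background([img], "PODXL")
        q = quantify_channel(img, "PODXL", bg, seg_params)
        assert abs(q.intact_fraction - truth.intact_fraction["PODXL"]) <= 0.05


class TestLiveDeadRatio:
    def _grid(self, n_px):
        grid = np.zeros((64, 64))
        grid.ravel()[:n_px] = 100.0
        return grid

    def test_two_to_one(self):
        params = SegmentationParams(threshold_offset=50)
        ratio, flagged = live_dead_ratio(self._grid(3000), self._grid(1500), 0.0, 0.0, params)
        assert ratio == pytest.approx(2.0)
        assert not flagged

    def test_identical_masks_give_one(self):
        params = SegmentationParams(threshold_offset=50)
        ratio, _ = live_dead_ratio(self._grid(800), self._grid(800), 0.0, 0.0, params)
        assert ratio == pytest.approx(1.0)

    def test_zero_red_area_flagged(self):
        params = SegmentationParams(threshold_offset=50)
        ratio, flagged = live_dead_ratio(self._grid(100), np.zeros((64, 64)), 0.0, 0.0, params)
        assert flagged and ratio == pytest.approx(100.0)

    def test_matches_mask_count_oracle(self, rng):
        params = SegmentationParams(threshold_offset=10, min_object_px=1)
        g = rng.uniform(0, 40, (32, 32))
        r = rng.uniform(0, 40, (32, 32))
        ratio, _ = live_dead_ratio(g, r, 5.0, 5.0, params)
        assert ratio == pytest.approx((g > 15).sum() / max((r > 15).sum(), 1))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimensions"):
            live_dead_ratio(np.zeros((4, 4)), np.zeros((5, 5)), 0, 0, SegmentationParams())


@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_masks_partition_surviving_area(seed):
    """Property: label map partitions the de-specked mask for any image."""
    rng = np.random.default_rng(seed)
    mask = rng.random((24, 24)) < 0.35
    labels = segment_components(mask, 8)
    assert np.array_equal(labels > 0, mask)
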