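"""Segmentation: K-means quantization, morphology, regions, patch cropping."""

import numpy as np
import pytest

from _oracles import flood_components, flood_fill_regions, minkowski_closing, minkowski_opening
from earcount.image_prep import rgb_to_lab
from earcount.segmentation import (
    EarRegion,
    QuantizedImage,
    SegmentationConfig,
    binarize,
    crop_patches,
    extract_regions,
    kmeans_quantize,
    morph_clean,
    pad_border,
    region_perimeter,
    segment_image,
    select_ear_cluster,
)

EAR_RGB = (212, 196, 88)
LEAF_RGB = (62, 124, 56)
SOIL_RGB = (118, 92, 62)


def _three_color_image():
    img = np.empty((30, 30, 3), dtype=np.uint8)
    img[:10] = EAR_RGB
    img[10:20] = LEAF_RGB
    img[20:] = SOIL_RGB
    return img


class TestKmeans:
    def test_three_pure_colors_recovered_exactly(self):
        img = _three_color_image()
        q = kmeans_quantize(img, SegmentationConfig(k=3, seed=0))
        expected = rgb_to_lab(img.reshape(1, -1, 3))[0]
        expected = np.unique(expected.round(6), axis=0)
        got = np.unique(q.centers.round(6), axis=0)
        np.testing.assert_allclose(got, expected, atol=1e-6)
        assert q.inertia == pytest.approx(0.0, abs=1e-9)

    def test_labels_are_nearest_center_assignments(self, rng):
        # independent per-pixel nearest-center oracle
        img = rng.integers(0, 256, (4, 5, 3), dtype=np.uint8)
        q = kmeans_quantize(img, SegmentationConfig(k=2, seed=7))
        lab = rgb_to_lab(img).reshape(-1, 3)
        d = ((lab[:, None, :] - q.centers[None, :, :]) ** 2).sum(axis=2)
        own = d[np.arange(len(lab)), q.labels.ravel()]
        assert (own <= d.min(axis=1) + 1e-9).all()
        assert q.inertia == pytest.approx(own.sum(), rel=1e-9)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConfig(k=1)

    def test_label_count_bounded_by_k(self, rng):
        img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        q = kmeans_quantize(img, SegmentationConfig(k=3, seed=1))
        assert len(np.unique(q.labels)) <= 3


class TestEarClusterSelection:
    def test_yellow_palette_center_selected(self):
        # b* of the three palette colors computed with the color oracle
        centers = rgb_to_lab(
            np.array([[SOIL_RGB, LEAF_RGB, EAR_RGB]], dtype=np.uint8)
        )[0]
        q = QuantizedImage(labels=np.zeros((2, 2), np.int32), centers=centers, inertia=0)
        b_star = centers[:, 2]
        assert np.argmax(b_star) == 2  # sanity: yellow has the largest b*
        assert select_ear_cluster(q) == 2

    def test_identical_centers_tie_breaks_to_lower_index(self):
        centers = np.array([[50.0, 0.0, 30.0], [50.0, 0.0, 30.0]])
        q = QuantizedImage(labels=np.zeros((1, 1), np.int32), centers=centers, inertia=0)
        assert select_ear_cluster(q) == 0

    def test_brightness_breaks_yellowness_ties(self):
        centers = np.array([[40.0, 0.0, 30.0], [70.0, 0.0, 30.0], [50.0, 0.0, 10.0]])
        q = QuantizedImage(labels=np.zeros((1, 1), np.int32), centers=centers, inertia=0)
        assert select_ear_cluster(q) == 1


class TestBinarize:
    def test_definition_on_small_label_grid(self):
        labels = np.array([[0, 1], [2, 0]], dtype=np.int32)
        q = QuantizedImage(labels=labels, centers=np.zeros((3, 3)), inertia=0)
        np.testing.assert_array_equal(binarize(q, 0), [[1, 0], [0, 1]])

    @pytest.mark.parametrize("ear_idx,expect", [(0, 1), (1, 0)])
    def test_all_or_nothing(self, ear_idx, expect):
        labels = np.zeros((3, 3), dtype=np.int32)
        q = QuantizedImage(labels=labels, centers=np.zeros((2, 3)), inertia=0)
        assert (binarize(q, ear_idx) == expect).all()

    def test_invalid_index_rejected(self):
        q = QuantizedImage(
            labels=np.zeros((2, 2), np.int32), centers=np.zeros((2, 3)), inertia=0
        )
        with pytest.raises(ValueError):
            binarize(q, 5)




class TestMorphology:
    def test_small_speck_removed_by_opening(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:7, 5:7] = 1  # 2x2 speck < 6x6 element
        assert morph_clean(mask).sum() == 0

    def test_small_hole_filled_by_closing(self):
        mask = np.ones((30, 30), dtype=np.uint8)
        mask[15, 15] = 0
        out = morph_clean(mask)
        assert out[15, 15] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_minkowski_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((40, 40)) < 0.45).astype(np.uint8)
        got = morph_clean(mask).astype(bool)
        se6 = np.ones((6, 6), dtype=bool)
        se3 = np.ones((3, 3), dtype=bool)
        want = minkowski_closing(minkowski_opening(mask.astype(bool), se6), se3)
        np.testing.assert_array_equal(got, want)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_opening_closing_idempotent_and_ordered(self, seed):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(seed)
        mask = rng.random((50, 50)) < 0.5
        se = np.ones((3, 3), dtype=bool)
        pad = 4
        mp = np.pad(mask, pad)
        opened = ndi.binary_opening(mp, se)
        closed = ndi.binary_closing(mp, se)
        # idempotence
        np.testing.assert_array_equal(ndi.binary_opening(opened, se), opened)
        np.testing.assert_array_equal(ndi.binary_closing(closed, se), closed)
        # opening never adds, closing never removes
        assert not (opened & ~mp).any()
        assert not (mp & ~closed).any()


class TestRegions:
    def test_five_disjoint_squares(self):
        mask = np.zeros((60, 60), dtype=np.uint8)
        tops = [(0, 0), (0, 25), (25, 0), (25, 25), (48, 48)]
        for r, c in tops:
            mask[r : r + 10, c : c + 10] = 1
        regions = extract_regions(mask, SegmentationConfig(min_area=50))
        assert len(regions) == 5
        for reg in regions:
            assert reg.area == 100
            assert reg.bbox[2:] == (10, 10)
            assert reg.perimeter == pytest.approx(4 * 9)
        assert [r.bbox[:2] for r in regions] == sorted(tops)

    def test_empty_mask_gives_empty_list(self):
        assert extract_regions(np.zeros((10, 10), np.uint8)) == []

    def test_diagonal_touch_is_one_region_under_8_connectivity(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:8, 2:8] = 1
        mask[8:14, 8:14] = 1  # touches only at the (7,7)-(8,8) diagonal
        regions = extract_regions(mask, SegmentationConfig(min_area=1))
        assert len(regions) == 1
        # a 4-connectivity flood-fill oracle sees two components
        assert flood_components(mask, diag=False) == 2
        assert flood_components(mask, diag=True) == 1

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((50, 50)) < 0.35).astype(np.uint8)
        regions = extract_regions(mask, SegmentationConfig(min_area=0))
        comps = flood_fill_regions(mask)
        assert len(regions) == len(comps)
        got = sorted((r.bbox, r.area) for r in regions)
        want = sorted(comps)
        assert got == want
        # area conservation at min_area = 0
        assert sum(r.area for r in regions) == int(mask.sum())

    def test_min_area_filters(self, rng):
        mask = (rng.random((50, 50)) < 0.35).astype(np.uint8)
        regions = extract_regions(mask, SegmentationConfig(min_area=10))
        assert all(r.area >= 10 for r in regions)
        assert sum(r.area for r in regions) <= int(mask.sum())

    def test_perimeter_of_line_and_pixel(self):
        line = np.zeros((3, 7), dtype=np.uint8)
        line[1, 1:6] = 1  # 1x5 line: walk 4 right + 4 back
        assert region_perimeter(line) == pytest.approx(8.0)
        single = np.zeros((3, 3), dtype=np.uint8)
        single[1, 1] = 1
        assert region_perimeter(single) == 0.0


class TestPadBorder:
    def test_width_zero_is_identity(self, rng):
        img = rng.integers(0, 256, (5, 5, 3), dtype=np.uint8)
        np.testing.assert_array_equal(pad_border(img, 0, (0, 0, 0)), img)

    def test_geometry_and_fill(self, rng):
        img = rng.integers(1, 256, (5, 5, 3), dtype=np.uint8)
        out = pad_border(img, 10, (9, 8, 7))
        assert out.shape == (25, 25, 3)
        np.testing.assert_array_equal(out[10:15, 10:15], img)
        np.testing.assert_array_equal(out[0, 0], [9, 8, 7])
        np.testing.assert_array_equal(out[-1, -1], [9, 8, 7])


class TestCropPatches:
    def test_exact_bbox_margin_zero_is_identity_crop(self, rng):
        img = rng.integers(0, 256, (200, 200, 3), dtype=np.uint8)
        reg = EarRegion(bbox=(20, 30, 100, 100), centroid=(70, 80), area=1, perimeter=0)
        cfg = SegmentationConfig(bbox_margin=0, patch_size=(100, 100))
        (patch,) = crop_patches(img, [reg], cfg)
        np.testing.assert_array_equal(patch, img[20:120, 30:130])

    def test_rectangular_bbox_scaled_to_square(self, rng):
        img = rng.integers(0, 256, (200, 200, 3), dtype=np.uint8)
        reg = EarRegion(bbox=(10, 10, 50, 80), centroid=(35, 50), area=1, perimeter=0)
        (patch,) = crop_patches(img, [reg], SegmentationConfig(bbox_margin=0))
        assert patch.shape == (100, 100, 3)

    def test_corner_region_clips_margin(self, rng):
        img = rng.integers(0, 256, (60, 60, 3), dtype=np.uint8)
        reg = EarRegion(bbox=(0, 0, 20, 20), centroid=(10, 10), area=1, perimeter=0)
        (patch,) = crop_patches(img, [reg], SegmentationConfig(bbox_margin=4))
        assert patch.shape == (100, 100, 3)

    def test_empty_region_list(self, rng):
        img = rng.integers(0, 256, (50, 50, 3), dtype=np.uint8)
        assert crop_patches(img, [], SegmentationConfig()) == []


class TestSegmentImage:
    def test_recovers_isolated_ears(self, small_scene):
        from earcount.image_prep import enhance

        scene, truth = small_scene
        regions, patches, mask = segment_image(enhance(scene), SegmentationConfig(seed=0))
        assert len(regions) == len(truth.blobs) == 8
        assert len(patches) == 8
        assert all(p.shape == (100, 100, 3) for p in patches)

    def test_all_green_image_yields_no_regions(self):
        img = np.full((80, 80, 3), (62, 124, 56), dtype=np.uint8)
        regions, patches, mask = segment_image(img, SegmentationConfig(seed=0))
        assert regions == []
        assert mask.sum() == 0

    def test_deterministic_for_fixed_seed(self, small_scene):
        scene, _ = small_scene
        cfg = SegmentationConfig(seed=11)
        r1, p1, m1 = segment_image(scene, cfg)
        r2, p2, m2 = segment_image(scene, cfg)
        assert r1 == r2
        np.testing.assert_array_equal(m1, m2)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)
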