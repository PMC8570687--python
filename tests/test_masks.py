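"""Tissue/vessel pixel classification and mask algebra against oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from shapely.geometry import box

from brainquant.annotations import Annotation, AnnotationSet
from brainquant.containers import BinaryMask, SectionImage
from brainquant.masks import (
    MaskParams,
    detect_tissue,
    detect_vessels,
    fill_small_holes,
    intersect_regions,
    remove_small_components,
    subtract,
)


def _img(dapi, pixel_size=1.0):
    """Three identical channels so the average equals each channel."""
    stack = np.stack([dapi, dapi, dapi]).astype(np.uint16)
    return SectionImage(stack, ("DAPI", "DsRed", "GFP"), pixel_size)


class TestDetectTissue:
    def test_uniform_below_threshold_is_empty(self):
        img = _img(np.full((64, 64), 30))
        with pytest.warns(UserWarning, match="empty"):
            mask = detect_tissue(img, MaskParams(min_area_um2=100, erode_um=0))
        assert mask.is_empty()

    def test_erosion_shrinks_square_by_radius_per_side(self):
        # 2 x 2 mm bright square at 2 um/px; erode 40 um -> 80 um shorter
        # than the unerorded mask (the Gaussian prefilter slightly dilates
        # the thresholded square, so the uneroded extent is the reference)
        ps = 2.0
        dapi = np.zeros((1200, 1200))
        dapi[100:1100, 100:1100] = 500  # 2000 x 2000 um
        def side(mask):
            rows = np.where(mask.data.any(axis=1))[0]
            return (rows[-1] - rows[0] + 1) * ps
        base = detect_tissue(
            _img(dapi, ps), MaskParams(min_hole_um2=0, min_fragment_um2=0, erode_um=0)
        )
        eroded = detect_tissue(
            _img(dapi, ps), MaskParams(min_hole_um2=0, min_fragment_um2=0)
        )
        assert abs((side(base) - side(eroded)) - 80) <= 2 * ps  # +-1 px per side

    def test_minimum_area_removes_small_tissue(self):
        # bright square of 500,000 um2 < 1,000,000 um2 minimum
        ps = 2.0
        dapi = np.zeros((500, 500))
        dapi[50:404, 50:404] = 500  # 708*708 = 501,264 um2
        with pytest.warns(UserWarning, match="empty"):
            mask = detect_tissue(_img(dapi, ps), MaskParams(erode_um=0))
        assert mask.is_empty()

    def test_requires_average_channel_mode(self):
        img = _img(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="average"):
            detect_tissue(img, MaskParams(channels_used="DAPI"))


class TestDetectVessels:
    def _dsred_img(self, dsred, ps=1.0):
        z = np.zeros_like(dsred)
        return SectionImage(
            np.stack([z, dsred, z]).astype(np.uint16), ("DAPI", "DsRed", "GFP"), ps
        )

    def test_bright_stripe_is_masked(self):
        dsred = np.zeros((200, 200))
        dsred[90:110, :] = 800  # 20 um wide stripe
        mask = detect_vessels(self._dsred_img(dsred))
        assert mask.data[100, 100]
        assert mask.data[95:105, 50:150].mean() > 0.9
        assert not mask.data[40, 100]

    def test_blob_below_minimum_size_removed(self):
        dsred = np.zeros((200, 200))
        dsred[100:110, 100:110] = 700  # 100 um2 < 150 um2 minimum
        assert detect_vessels(self._dsred_img(dsred)).is_empty()

    def test_no_signal_above_threshold_is_empty(self):
        dsred = np.full((64, 64), 300.0)  # below the 400 default
        assert detect_vessels(self._dsred_img(dsred)).is_empty()

    def test_rejects_average_mode(self):
        with pytest.raises(ValueError, match="single channel"):
            detect_vessels(
                self._dsred_img(np.zeros((8, 8))), MaskParams.vessels(channels_used="average")
            )


class TestMaskAlgebra:
    def test_subtract_identity_and_self(self):
        rng = np.random.default_rng(0)
        a = BinaryMask(rng.random((32, 32)) > 0.5, 1.0)
        empty = BinaryMask.empty(a.shape, 1.0)
        assert np.array_equal(subtract(a, empty).data, a.data)
        assert subtract(a, a).is_empty()

    def test_subtract_area_arithmetic(self):
        rng = np.random.default_rng(1)
        a = BinaryMask(rng.random((64, 64)) > 0.4, 1.0)
        b = BinaryMask(rng.random((64, 64)) > 0.6, 1.0)
        res = subtract(a, b)
        overlap = (a.data & b.data).sum()
        assert res.data.sum() == a.data.sum() - overlap

    def test_subtract_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(2)
        a = BinaryMask(rng.random((64, 64)) > 0.5, 1.0)
        b = BinaryMask(rng.random((64, 64)) > 0.5, 1.0)
        res = subtract(a, b).data
        for i in range(64):
            for j in range(64):
                assert res[i, j] == (a.data[i, j] and not b.data[i, j])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            subtract(BinaryMask.full((4, 4), 1.0), BinaryMask.full((5, 5), 1.0))


class TestIntersectRegions:
    def test_region_inside_tissue_has_polygon_area(self):
        tissue = BinaryMask.full((100, 100), 1.0)
        region = Annotation("r", box(10, 20, 60, 80))
        out = intersect_regions(tissue, AnnotationSet([region]))
        assert out["r"].data.sum() == pytest.approx(50 * 60, abs=120)

    def test_region_outside_tissue_is_empty(self):
        tissue = BinaryMask.empty((100, 100), 1.0)
        out = intersect_regions(tissue, AnnotationSet([Annotation("r", box(0, 0, 50, 50))]))
        assert out["r"].is_empty()

    def test_disjoint_regions_give_disjoint_masks(self):
        tissue = BinaryMask.full((100, 100), 1.0)
        regions = AnnotationSet(
            [Annotation("a", box(0, 0, 50, 100)), Annotation("b", box(50, 0, 100, 100))]
        )
        out = intersect_regions(tissue, regions)
        assert not (out["a"].data & out["b"].data).any()

    def test_unknown_region_name_raises(self):
        tissue = BinaryMask.full((10, 10), 1.0)
        with pytest.raises(KeyError, match="nope"):
            intersect_regions(
                tissue, AnnotationSet([Annotation("r", box(0, 0, 5, 5))]), names=["nope"]
            )


class TestCleanupHelpers:
    def test_small_component_removal_is_strict_inequality(self):
        binary = np.zeros((20, 20), bool)
        binary[2:4, 2:4] = True  # area 4
        assert remove_small_components(binary, 5).sum() == 0
        assert remove_small_components(binary, 4).sum() == 4

    def test_hole_filling_only_adds_interior_pixels(self):
        binary = np.ones((20, 20), bool)
        binary[8:10, 8:10] = False  # 4-px hole
        binary[0, 0] = False  # border notch, not a hole
        filled = fill_small_holes(binary, 5)
        assert filled[8, 8] and not filled[0, 0]
        assert (filled & ~binary).sum() == 4

    def test_cleanup_is_monotone_after_thresholding(self):
        """Every stage only removes pixels, except hole filling which only
        adds pixels strictly inside components."""
        rng = np.random.default_rng(3)
        raw = rng.normal(60, 40, (96, 96)).clip(0)
        p = MaskParams(
            threshold=80, min_hole_um2=20, min_area_um2=30, erode_um=2, min_fragment_um2=10
        )
        sm = ndi.gaussian_filter(raw, p.smoothing_sigma_px)
        base = fill_small_holes(sm >= p.threshold, p.min_hole_um2)
        img = _img(raw)
        final = detect_tissue(img, p)
        assert not (final.data & ~base).any()

    def test_erosion_matches_disc_structuring_element(self):
        from skimage.morphology import disk

        rng = np.random.default_rng(4)
        binary = ndi.binary_dilation(rng.random((64, 64)) > 0.97, iterations=6)
        from brainquant.masks import _erode_by_disc

        ours = _erode_by_disc(binary, 3)
        reference = ndi.binary_erosion(binary, structure=disk(3), border_value=1)
        # a pixel survives disc erosion iff no background pixel lies within
        # Euclidean distance r, which is exactly edt > r
        assert np.array_equal(ours, reference)
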