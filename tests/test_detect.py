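"""Nucleus detection, watershed splitting, expansion and measurement."""

import numpy as np
import pytest

from brainquant.containers import BinaryMask, SectionImage
from brainquant.detect import (
    DetectionParams,
    detect_and_measure,
    detect_nuclei,
    expand_cells,
    measure_intensities,
)
from brainquant.evaluate import match_detections
from brainquant.masks import detect_tissue, MaskParams
from brainquant.synthetic import generate_section
from tests.conftest import disc_image, small_config, small_tissue_params


def _full_mask(img):
    return BinaryMask.full(img.shape, img.pixel_size_um)


class TestDetectNuclei:
    def test_blank_image_gives_no_detections(self):
        img = disc_image([], shape=(64, 64))
        dets = detect_nuclei(img, _full_mask(img), DetectionParams(threshold=150))
        assert len(dets) == 0

    def test_missing_dapi_channel_raises(self):
        img = disc_image([(10, 10)])
        broken = SectionImage(img.pixels, ("a", "b", "c"), 1.0)
        with pytest.raises(ValueError, match="DAPI"):
            detect_nuclei(broken, None, DetectionParams())

    def test_well_separated_nuclei_all_found_once(self):
        """Ground-truth count is recovered exactly across the plateau of
        thresholds between background and foreground intensity."""
        cfg = small_config(
            seed=5,
            dim_fraction=0.0,
            touching_fraction=0.0,
            nucleus_density={"cortex": 600.0, "thalamus": 600.0},
            edge_brightening_amplitude=0.0,  # counting test, no edge band
        )
        img, cells, _ = generate_section(cfg)
        mask = _full_mask(img)
        for threshold in (100, 125, 150):
            dets = detect_nuclei(img, mask, DetectionParams(threshold=threshold))
            assert len(dets) == len(cells)

    def test_touching_pair_split_by_watershed(self):
        img = disc_image([(30, 32), (37, 32)], radius_um=4.0, shape=(64, 64))
        dets = detect_nuclei(img, _full_mask(img), DetectionParams(threshold=500))
        assert len(dets) == 2

    def test_single_disc_is_one_detection_with_true_area(self):
        img = disc_image([(32, 32)], radius_um=4.0, shape=(64, 64))
        dets = detect_nuclei(
            img, _full_mask(img), DetectionParams(threshold=500, sigma_px=0)
        )
        assert len(dets) == 1
        assert dets.table["nucleus_area_um2"].iloc[0] == pytest.approx(
            np.pi * 16, rel=0.15
        )
        assert dets.table["centroid_x_um"].iloc[0] == pytest.approx(32, abs=0.6)

    def test_area_bounds_filter_detections(self):
        img = disc_image([(32, 32)], radius_um=4.0, shape=(64, 64))
        small = detect_nuclei(
            img, _full_mask(img), DetectionParams(threshold=500, max_area_um2=20)
        )
        assert len(small) == 0

    def test_detections_outside_mask_dropped(self):
        img = disc_image([(16, 16), (48, 48)], shape=(64, 64))
        half = np.zeros((64, 64), bool)
        half[:32] = True
        dets = detect_nuclei(img, BinaryMask(half, 1.0), DetectionParams(threshold=500))
        assert len(dets) == 1
        assert dets.table["centroid_y_um"].iloc[0] < 32

    def test_determinism(self):
        cfg = small_config(seed=9)
        img, _, _ = generate_section(cfg)
        a = detect_and_measure(img, _full_mask(img), DetectionParams(threshold=150))
        b = detect_and_measure(img, _full_mask(img), DetectionParams(threshold=150))
        assert a.table.equals(b.table)
        assert np.array_equal(a.cell_labels, b.cell_labels)


class TestExpandCells:
    def test_zero_expansion_is_identity(self):
        img = disc_image([(32, 32)])
        dets = detect_nuclei(img, _full_mask(img), DetectionParams(threshold=500))
        out = expand_cells(dets, 0.0, _full_mask(img))
        assert np.array_equal(out.cell_labels, out.nucleus_labels)

    def test_isolated_nucleus_grows_to_annulus_area(self):
        img = disc_image([(32, 32)], radius_um=4.0, shape=(64, 64))
        dets = detect_nuclei(
            img, _full_mask(img), DetectionParams(threshold=500, sigma_px=0)
        )
        out = expand_cells(dets, 2.0, _full_mask(img))
        cell_area = (out.cell_labels == 1).sum()
        assert cell_area == pytest.approx(np.pi * 6**2, rel=0.12)

    def test_competing_expansions_meet_at_midline(self):
        img = disc_image([(28, 32), (39, 32)], radius_um=4.0, shape=(64, 64))
        dets = detect_nuclei(
            img, _full_mask(img), DetectionParams(threshold=500, sigma_px=0)
        )
        out = expand_cells(dets, 2.0, _full_mask(img))
        assert len(out) == 2
        # brute-force nearest-nucleus oracle on the expansion ring
        ys, xs = np.nonzero(out.cell_labels)
        nuc = out.nucleus_labels
        from scipy import ndimage as ndi

        dist_to = [
            ndi.distance_transform_edt(nuc != k) for k in (1, 2)
        ]
        for y, x in zip(ys, xs):
            lbl = out.cell_labels[y, x]
            if nuc[y, x]:
                continue
            d1, d2 = dist_to[0][y, x], dist_to[1][y, x]
            expected = 1 if d1 < d2 else 2 if d2 < d1 else lbl
            assert lbl == expected

    def test_nucleus_always_inside_cell(self):
        cfg = small_config(seed=6)
        img, _, _ = generate_section(cfg)
        mask = detect_tissue(img, MaskParams(min_area_um2=1000))
        dets = detect_nuclei(img, mask, DetectionParams(threshold=150))
        out = expand_cells(dets, 2.0, mask)
        nz = out.nucleus_labels > 0
        assert np.array_equal(out.cell_labels[nz], out.nucleus_labels[nz])


class TestMeasureIntensities:
    def test_uniform_channel_gives_uniform_means(self):
        img = disc_image([(32, 32)], background=0.0)
        img.pixels[1, :, :] = 77  # DsRed uniform
        dets = detect_nuclei(img, _full_mask(img), DetectionParams(threshold=500))
        dets = expand_cells(dets, 2.0, _full_mask(img))
        dets = measure_intensities(dets, img)
        assert dets.table["cell_mean_DsRed"].iloc[0] == pytest.approx(77)
        assert dets.table["nucleus_mean_DsRed"].iloc[0] == pytest.approx(77)

    def test_half_bright_cell_mean_is_midpoint(self):
        img = disc_image([(32, 32)], radius_um=4.0)
        gfp = np.zeros((128, 128))
        gfp[:, 32:] = 1000  # split exactly through the disc center
        img.pixels[2] = gfp.astype(np.uint16)
        dets = detect_nuclei(
            img, _full_mask(img), DetectionParams(threshold=500, sigma_px=0)
        )
        dets = measure_intensities(dets, img)
        assert dets.table["nucleus_mean_GFP"].iloc[0] == pytest.approx(500, rel=0.1)

    def test_ring_only_marker_raises_cell_mean_above_nucleus_mean(self):
        img = disc_image([(32, 32)], radius_um=4.0)
        yy, xx = np.mgrid[0:128, 0:128]
        r2 = (xx + 0.5 - 32) ** 2 + (yy + 0.5 - 32) ** 2
        ring = (r2 > 4.0**2) & (r2 <= 6.5**2)
        img.pixels[1][ring] = 900  # DsRed only outside the nucleus
        dets = detect_nuclei(
            img, _full_mask(img), DetectionParams(threshold=500, sigma_px=0)
        )
        dets = expand_cells(dets, 2.0, _full_mask(img))
        dets = measure_intensities(dets, img)
        row = dets.table.iloc[0]
        assert row["cell_mean_DsRed"] > row["nucleus_mean_DsRed"] + 100


def test_detection_recall_on_default_sections_is_high():
    """Inside the eroded tissue mask (the pipeline's analysis area, which
    excludes the brightened tissue edge) nearly all cells are found and
    few detections lack a ground-truth counterpart."""
    cfg = small_config(seed=12)
    img, cells, _ = generate_section(cfg)
    mask = detect_tissue(img, small_tissue_params())
    dets = detect_and_measure(img, mask, DetectionParams(threshold=150))
    m = match_detections(cells, dets, within=mask)
    assert m.recall_pct() > 95.0
    assert m.spurious_pct() < 5.0
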