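"""Desk-scale reproduction of the full optimization-and-quantification study.

Builds a cohort of synthetic sections, optimizes the DAPI detection
threshold and the DsRed/GFP classification thresholds against
ground-truth counts in 300 x 200 um test annotations (the stand-in for
manual counting), then applies the optimized per-region thresholds to
whole sections to score detection fidelity and recover per-region class
percentages and densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .annotations import AnnotationSet
from .classify import ClassifierParams, classify_cells
from .containers import BinaryMask, SectionImage
from .detect import DetectionParams, Detections, detect_and_measure
from .evaluate import TRUE_TO_PREDICTED, match_detections
from .masks import MaskParams, detect_tissue, detect_vessels, intersect_regions, subtract
from .optimize import (
    CLASSIFIER_DSRED,
    CLASSIFIER_GFP,
    DETECTION_THRESHOLD,
    Optimum,
    SweepAnnotation,
    SweepSpec,
    SweepResult,
    ThresholdSweep,
)
from .quantify import RegionQuantification, quantify_region, summarize
from .synthetic import (
    GroundTruthCell,
    SectionConfig,
    generate_section,
    generate_test_annotations,
    ground_truth_counts,
)

__all__ = [
    "Cohort",
    "build_cohort",
    "build_sweep_annotations",
    "run_threshold_study",
    "ThresholdStudy",
    "region_detections",
    "score_fidelity",
    "FidelityScore",
    "quantify_cohort",
]

GRIDS = {
    "dapi": (DETECTION_THRESHOLD, 50.0, 1000.0, 25.0),
    "dsred": (CLASSIFIER_DSRED, 200.0, 550.0, 25.0),
    "gfp": (CLASSIFIER_GFP, 100.0, 450.0, 25.0),
}


@dataclass
class Cohort:
    """Generated sections with their masks and exhaustive ground truth."""

    sections: dict[str, SectionImage]
    analyzed: dict[str, BinaryMask]  # tissue minus large vessels
    annotations: dict[str, AnnotationSet]
    truths: dict[str, list[GroundTruthCell]]
    base_config: SectionConfig

    @property
    def region_names(self) -> list[str]:
        return [name for name, _ in self.base_config.regions]


def build_cohort(n_sections: int = 8, seed: int = 0, **section_overrides) -> Cohort:
    """Generate a cohort of sections with detected tissue/vessel masks."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sections)]
    sections, analyzed, annotations, truths = {}, {}, {}, {}
    base = SectionConfig(**section_overrides, seed=child_seeds[0])
    for i, sd in enumerate(child_seeds):
        sid = f"section-{i:02d}"
        cfg = SectionConfig(**section_overrides, seed=sd)
        img, cells, annots = generate_section(cfg)
        tissue = detect_tissue(img, MaskParams.tissue())
        vessels = detect_vessels(img, MaskParams.vessels())
        sections[sid] = img
        analyzed[sid] = subtract(tissue, vessels)
        annotations[sid] = annots
        truths[sid] = cells
    return Cohort(sections, analyzed, annotations, truths, base)


def build_sweep_annotations(
    cohort: Cohort, seed: int = 0, size_um: tuple[float, float] = (300.0, 200.0)
) -> dict[str, list[SweepAnnotation]]:
    """One test rectangle per (section, region) with ground-truth counts.

    Rectangles avoid large synthetic vessels, as manual-count ROIs are
    drawn in clean tissue.
    """
    out: dict[str, list[SweepAnnotation]] = {"dapi": [], "dsred": [], "gfp": []}
    for i, (sid, img) in enumerate(cohort.sections.items()):
        vessel_annots = cohort.annotations[sid].by_role("vessels")
        avoid = (
            unary_union([a.geometry for a in vessel_annots]).buffer(10.0)
            if vessel_annots
            else None
        )
        rects = generate_test_annotations(
            cohort.annotations[sid],
            size_um,
            seed=seed + i,
            pixel_size_um=img.pixel_size_um,
            avoid=avoid,
        )
        for rect in rects:
            counts = ground_truth_counts(
                cohort.truths[sid], rect.to_um(img.pixel_size_um)
            )
            for key, mc in zip(("dapi", "dsred", "gfp"), counts):
                out[key].append(SweepAnnotation(sid, rect.name, rect.geometry, mc))
    return out


@dataclass
class ThresholdStudy:
    """Results of the three sweeps plus the selected per-region thresholds."""

    sweeps: dict[str, SweepResult]
    pooled: dict[str, Optimum]
    by_region: dict[str, dict[str, float]]  # region -> {dapi, dsred, gfp}
    gaps: dict[str, tuple[float, float]]  # channel key -> (neg max, pos min)

    def detection_params(self) -> dict[str, DetectionParams]:
        return {
            r: DetectionParams(threshold=t["dapi"]) for r, t in self.by_region.items()
        }

    def classifier_params(self) -> dict[str, ClassifierParams]:
        return {
            r: ClassifierParams(r, t["dsred"], t["gfp"])
            for r, t in self.by_region.items()
        }


def run_threshold_study(cohort: Cohort, seed: int = 0) -> ThresholdStudy:
    """Sweep DAPI, then DsRed and GFP at the optimized DAPI thresholds."""
    annots = build_sweep_annotations(cohort, seed=seed)
    sweeps: dict[str, SweepResult] = {}
    pooled: dict[str, Optimum] = {}
    by_region: dict[str, dict[str, float]] = {}

    param, start, stop, step = GRIDS["dapi"]
    spec = SweepSpec(param, start, stop, step, tuple(annots["dapi"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ThresholdSweep(spec, cohort.sections, cohort.analyzed).fit()
    sweeps["dapi"] = res
    pooled["dapi"] = res.select_optimum()
    dapi_by_region = res.optimum_by_region()
    for r, opt in dapi_by_region.items():
        by_region[r] = {"dapi": opt.value}
    det_by_region = {
        r: DetectionParams(threshold=opt.value) for r, opt in dapi_by_region.items()
    }

    for key in ("dsred", "gfp"):
        param, start, stop, step = GRIDS[key]
        spec = SweepSpec(param, start, stop, step, tuple(annots[key]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ThresholdSweep(
                spec, cohort.sections, cohort.analyzed, det_by_region
            ).fit()
        sweeps[key] = res
        pooled[key] = res.select_optimum()
        regional = res.optimum_by_region()
        for r in by_region:
            by_region[r][key] = (
                regional[r].value if r in regional else pooled[key].value
            )

    gaps = _measure_gaps(cohort, annots, det_by_region)
    return ThresholdStudy(sweeps, pooled, by_region, gaps)


def _measure_gaps(
    cohort: Cohort,
    annots: dict[str, list[SweepAnnotation]],
    det_by_region: Mapping[str, DetectionParams],
) -> dict[str, tuple[float, float]]:
    """Empirical separating gap (max negative, min positive cell mean)
    per marker channel, over the cells inside the test annotations."""
    from shapely.affinity import translate

    from .annotations import rasterize_geometry
    from .detect import detect_nuclei, expand_cells, measure_intensities

    neg: dict[str, list[float]] = {"dsred": [], "gfp": []}
    pos: dict[str, list[float]] = {"dsred": [], "gfp": []}
    channel_of = {"dsred": "DsRed", "gfp": "GFP"}
    class_of = {"dsred": "pericyte", "gfp": "microglia"}
    for a in annots["dapi"]:
        img = cohort.sections[a.section_id]
        ps = img.pixel_size_um
        minx, miny, maxx, maxy = a.rectangle.bounds
        pad = 16
        r0, r1 = max(int(miny) - pad, 0), min(int(maxy) + pad, img.height)
        c0, c1 = max(int(minx) - pad, 0), min(int(maxx) + pad, img.width)
        crop = img.crop(r0, r1, c0, c1)
        rect_local = translate(a.rectangle, xoff=-c0, yoff=-r0)
        within = rasterize_geometry(rect_local, crop.shape)
        within &= cohort.analyzed[a.section_id].data[r0:r1, c0:c1]
        mask = BinaryMask(within, ps)
        params = det_by_region[a.region]
        dets = detect_nuclei(crop, mask, params)
        dets = expand_cells(dets, params.cell_expansion_um, mask)
        dets = measure_intensities(dets, crop)
        local_cells = [
            GroundTruthCell(
                i, c.x_um - c0 * ps, c.y_um - r0 * ps, c.radius_um, c.cell_class, c.region
            )
            for i, c in enumerate(cohort.truths[a.section_id])
            if minx * ps <= c.x_um <= maxx * ps and miny * ps <= c.y_um <= maxy * ps
        ]
        match = match_detections(local_cells, dets, within=mask)
        for key in ("dsred", "gfp"):
            means = dets.table[f"cell_mean_{channel_of[key]}"].to_numpy(dtype=float)
            for g, d in enumerate(match.gt_to_det):
                if d < 0:
                    continue
                bucket = pos if local_cells[g].cell_class == class_of[key] else neg
                bucket[key].append(float(means[d]))
    return {
        key: (
            max(neg[key]) if neg[key] else float("nan"),
            min(pos[key]) if pos[key] else float("nan"),
        )
        for key in ("dsred", "gfp")
    }


@dataclass
class FidelityScore:
    recall_pct: float
    spurious_pct: float
    classification_accuracy_pct: float
    n_ground_truth: int
    n_detections: int


def region_detections(
    cohort: Cohort, study: ThresholdStudy
) -> dict[str, dict[str, tuple[Detections, BinaryMask]]]:
    """Classified detections per (section, region) at the studied thresholds.

    Sections are detected once per distinct DAPI threshold and split into
    regions by nucleus centroid afterwards.
    """
    out: dict[str, dict[str, tuple[Detections, BinaryMask]]] = {}
    for sid, img in cohort.sections.items():
        region_masks = intersect_regions(cohort.analyzed[sid], cohort.annotations[sid])
        thresholds = {study.by_region[r]["dapi"] for r in region_masks}
        per_threshold: dict[float, Detections] = {}
        for t in thresholds:
            per_threshold[t] = detect_and_measure(
                img, cohort.analyzed[sid], DetectionParams(threshold=t)
            )
        out[sid] = {}
        for region, rmask in region_masks.items():
            dets = per_threshold[study.by_region[region]["dapi"]]
            ps = rmask.pixel_size_um
            rows = np.clip(
                (dets.table["centroid_y_um"].to_numpy() / ps - 0.5).round().astype(int),
                0,
                rmask.shape[0] - 1,
            )
            cols = np.clip(
                (dets.table["centroid_x_um"].to_numpy() / ps - 0.5).round().astype(int),
                0,
                rmask.shape[1] - 1,
            )
            inside = rmask.data[rows, cols] if len(dets) else np.zeros(0, bool)
            sub = Detections(
                dets.nucleus_labels,
                dets.cell_labels,
                dets.table[inside].copy(),
                dets.pixel_size_um,
                dets.channel_names,
            )
            sub = classify_cells(sub, study.classifier_params()[region])
            out[sid][region] = (sub, rmask)
    return out


def score_fidelity(
    cohort: Cohort, study: ThresholdStudy, per_region=None
) -> FidelityScore:
    """Detection recall, spurious rate and class accuracy at the optima."""
    recalls_n = recalls_hit = spur_n = spur_miss = 0
    acc_hit = acc_n = 0
    if per_region is None:
        per_region = region_detections(cohort, study)
    for sid, regions in per_region.items():
        for region, (dets, rmask) in regions.items():
            cells = [c for c in cohort.truths[sid] if c.region == region]
            match = match_detections(cells, dets, within=rmask)
            in_mask = match.gt_in_mask
            recalls_n += int(in_mask.sum())
            recalls_hit += int((match.gt_to_det[in_mask] >= 0).sum())
            spur_n += len(dets)
            spur_miss += int((match.det_to_gt < 0).sum())
            pred = dets.table["cell_class"].to_numpy()
            for g, d in enumerate(match.gt_to_det):
                if d < 0 or not in_mask[g]:
                    continue
                acc_n += 1
                acc_hit += pred[d] == TRUE_TO_PREDICTED[cells[g].cell_class]
    return FidelityScore(
        recall_pct=100.0 * recalls_hit / recalls_n if recalls_n else float("nan"),
        spurious_pct=100.0 * spur_miss / spur_n if spur_n else float("nan"),
        classification_accuracy_pct=100.0 * acc_hit / acc_n if acc_n else float("nan"),
        n_ground_truth=recalls_n,
        n_detections=spur_n,
    )


def quantify_cohort(
    cohort: Cohort, study: ThresholdStudy, per_region=None
) -> tuple[list[RegionQuantification], pd.DataFrame]:
    """Per-(section, region) quantifications and the summary table."""
    if per_region is None:
        per_region = region_detections(cohort, study)
    quants = []
    for sid, regions in per_region.items():
        for region, (dets, rmask) in regions.items():
            quants.append(quantify_region(dets, rmask, sid, region))
    return quants, summarize(quants)
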