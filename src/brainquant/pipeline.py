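"""End-to-end orchestration: generate/load → mask → detect → classify → quantify.

A run is driven by a single config dict (usually loaded from YAML).  For
synthetic runs the config carries a section-generator block and a number
of sections; a single global seed is expanded into per-section
substreams.  Optionally the run optimizes the DAPI/DsRed/GFP thresholds
against ground-truth counts in test annotations before classifying
(config key ``optimize: true``); otherwise per-region thresholds come
from the config or the built-in defaults.  Every stage writes its
artifacts under the output directory and the run ends with a manifest
recording parameters and content hashes, so identical configs produce
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from . import io as bio
from .classify import (
    ClassifierParams,
    REGION_THRESHOLD_DEFAULTS,
    classify_cells,
    write_classifier_params,
)
from .containers import BinaryMask, SectionImage
from .detect import DetectionParams, detect_nuclei, expand_cells, measure_intensities
from .masks import MaskParams, detect_tissue, detect_vessels, intersect_regions, subtract
from .optimize import (
    CLASSIFIER_DSRED,
    CLASSIFIER_GFP,
    DETECTION_THRESHOLD,
    SweepAnnotation,
    SweepSpec,
    ThresholdSweep,
)
from .quantify import quantify_region, summarize
from .synthetic import (
    SectionConfig,
    generate_section,
    generate_test_annotations,
    ground_truth_counts,
    write_ground_truth,
)

log = logging.getLogger("brainquant")

__all__ = ["run_pipeline", "validate_config", "DEFAULT_SWEEPS"]

# the published grid for each swept threshold: (parameter, start, stop, step)
DEFAULT_SWEEPS = {
    "dapi": (DETECTION_THRESHOLD, 50, 1000, 25),
    "dsred": (CLASSIFIER_DSRED, 200, 550, 25),
    "gfp": (CLASSIFIER_GFP, 100, 450, 25),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: Mapping) -> None:
    if "classifiers" in config and config.get("optimize"):
        raise ValueError(
            "config sets both fixed 'classifiers' and 'optimize'; choose one"
        )
    if "synthetic" not in config and "images" not in config:
        raise ValueError("config needs a 'synthetic' block or an 'images' list")


def _load_sections(config: Mapping, seed: int, out: Path):
    """Generate synthetic sections (or read existing ones) plus annotations."""
    sections: dict[str, SectionImage] = {}
    annotations: dict[str, object] = {}
    truths: dict[str, list] = {}
    if "synthetic" in config:
        syn = dict(config["synthetic"])
        n_sections = int(syn.pop("n_sections", 1))
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sections)]
        gen_dir = out / "sections"
        gen_dir.mkdir(parents=True, exist_ok=True)
        for i, sd in enumerate(child_seeds):
            sid = f"section-{i:02d}"
            cfg = SectionConfig(**syn, seed=sd)
            img, cells, annot = generate_section(cfg)
            sections[sid] = img
            annotations[sid] = annot
            truths[sid] = cells
            bio.write_section(img, gen_dir / f"{sid}.tif")
            write_ground_truth(cells, gen_dir / f"{sid}-truth.csv")
            bio.write_annotations(annot, gen_dir / f"{sid}-annotations.geojson")
        log.info("generated %d synthetic sections", n_sections)
    else:
        for entry in config["images"]:
            sid = entry.get("id") or Path(entry["path"]).stem
            sections[sid] = bio.read_section(
                entry["path"], entry.get("pixel_size_um")
            )
            annotations[sid] = bio.read_annotations(entry["annotations"])
    return sections, annotations, truths


def run_pipeline(config: Mapping, output_dir, seed: int | None = None) -> dict:
    """Run the full pipeline from a config; returns the manifest dict."""
    validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)

    sections, annotations, truths = _load_sections(config, seed, out)

    # ---- stage: masks ----------------------------------------------------
    tissue_params = MaskParams.tissue(**config.get("mask", {}).get("tissue", {}))
    vessel_params = MaskParams.vessels(**config.get("mask", {}).get("vessels", {}))
    analyzed: dict[str, BinaryMask] = {}
    region_masks: dict[str, dict[str, BinaryMask]] = {}
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for sid, img in sections.items():
        tissue = detect_tissue(img, tissue_params)
        vessels = detect_vessels(img, vessel_params)
        analyzed[sid] = subtract(tissue, vessels)
        region_masks[sid] = intersect_regions(analyzed[sid], annotations[sid])
        tifffile.imwrite(
            mask_dir / f"{sid}-analyzed.tif", analyzed[sid].data.astype(np.uint8)
        )
    log.info("masked %d sections", len(sections))

    # ---- stage: threshold selection -------------------------------------
    region_names = sorted(
        {name for sid in sections for name in region_masks[sid]}
    )
    if config.get("optimize"):
        thresholds = _optimize_thresholds(
            config, sections, analyzed, annotations, truths, seed, out
        )
    else:
        thresholds = {}
        for region in region_names:
            base = REGION_THRESHOLD_DEFAULTS.get(
                region, {"dapi": 150, "dsred": 375, "gfp": 250}
            )
            override = config.get("classifiers", {}).get(region, {})
            thresholds[region] = {
                "dapi": override.get("dapi_threshold", base["dapi"]),
                "dsred": override.get("dsred_threshold", base["dsred"]),
                "gfp": override.get("gfp_threshold", base["gfp"]),
            }
    write_classifier_params(
        {
            r: ClassifierParams(r, t["dsred"], t["gfp"])
            for r, t in thresholds.items()
        },
        out / "classifiers.json",
    )

    # ---- stage: detection, classification, quantification ----------------
    det_overrides = config.get("detection", {})
    det_dir = out / "detections"
    det_dir.mkdir(exist_ok=True)
    quants = []
    for sid, img in sections.items():
        for region, rmask in region_masks[sid].items():
            if rmask.is_empty():
                log.warning("empty analyzed mask for %s/%s; skipped", sid, region)
                continue
            t = thresholds[region]
            params = DetectionParams(**{**det_overrides, "threshold": t["dapi"]})
            dets = detect_nuclei(img, rmask, params)
            dets = expand_cells(dets, params.cell_expansion_um, rmask)
            dets = measure_intensities(dets, img)
            dets = classify_cells(dets, ClassifierParams(region, t["dsred"], t["gfp"]))
            dets.to_csv(det_dir / f"{sid}-{region}.csv")
            quants.append(quantify_region(dets, rmask, sid, region))
    bio.write_measurements(quants, out / "measurements.csv")
    summarize(quants).to_csv(out / "summary.csv", index=False)
    log.info("quantified %d (section, region) pairs", len(quants))

    # ---- manifest --------------------------------------------------------
    files = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    manifest = {
        "seed": seed,
        "config": json.loads(json.dumps(config, default=str)),
        "thresholds": thresholds,
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _optimize_thresholds(
    config, sections, analyzed, annotations, truths, seed, out
) -> dict[str, dict[str, float]]:
    """Sweep DAPI, DsRed and GFP thresholds against ground-truth counts."""
    if not truths:
        raise ValueError("threshold optimization requires synthetic ground truth")
    size = tuple(config.get("test_annotation_um", (300.0, 200.0)))
    sweep_annots: dict[str, list[SweepAnnotation]] = {"dapi": [], "dsred": [], "gfp": []}
    for i, (sid, img) in enumerate(sections.items()):
        # test rectangles are drawn in clean tissue, away from large vessels
        vessel_annots = annotations[sid].by_role("vessels")
        avoid = None
        if vessel_annots:
            from shapely.ops import unary_union

            avoid = unary_union([a.geometry for a in vessel_annots]).buffer(10.0)
        rects = generate_test_annotations(
            annotations[sid],
            size,
            seed=seed + i,
            pixel_size_um=img.pixel_size_um,
            avoid=avoid,
        )
        for rect in rects:
            counts = ground_truth_counts(
                truths[sid], rect.to_um(img.pixel_size_um)
            )
            for key, mc in zip(("dapi", "dsred", "gfp"), counts):
                sweep_annots[key].append(
                    SweepAnnotation(sid, rect.name, rect.geometry, mc)
                )

    thresholds: dict[str, dict[str, float]] = {}
    # DAPI first; its per-region optimum feeds the classification sweeps
    param, start, stop, step = DEFAULT_SWEEPS["dapi"]
    spec = SweepSpec(param, start, stop, step, tuple(sweep_annots["dapi"]))
    result = ThresholdSweep(spec, sections, analyzed).fit()
    result.to_csv(out / "sweep-dapi.csv")
    dapi_opt = result.optimum_by_region()
    det_by_region = {
        r: DetectionParams(threshold=opt.value) for r, opt in dapi_opt.items()
    }
    for r, opt in dapi_opt.items():
        thresholds[r] = {"dapi": opt.value}

    for key in ("dsred", "gfp"):
        param, start, stop, step = DEFAULT_SWEEPS[key]
        spec = SweepSpec(param, start, stop, step, tuple(sweep_annots[key]))
        result = ThresholdSweep(spec, sections, analyzed, det_by_region).fit()
        result.to_csv(out / f"sweep-{key}.csv")
        by_region = result.optimum_by_region()
        pooled = result.select_optimum()
        for r in thresholds:
            # regions whose annotations all lacked positive manual counts
            # fall back to the optimum pooled over all regions
            thresholds[r][key] = by_region[r].value if r in by_region else pooled.value
    return thresholds
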