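"""Four-way intensity classification of detected cells.

A cell is DsRed-positive iff its cell-mean DsRed intensity is at or above
the region's DsRed threshold (inclusive ``>=``), GFP-positive analogously;
cells above both thresholds are DUAL (usually an artifact of adjacent,
unseparated nuclei) and cells above neither are NEGATIVE.  The partition
is exhaustive and exclusive, and DUAL cells are tallied separately —
they do not count toward the pericyte or microglia totals.
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .detect import Detections

__all__ = [
    "CellClass",
    "ClassifierParams",
    "classify_cells",
    "class_counts",
    "ClassCounts",
    "REGION_THRESHOLD_DEFAULTS",
    "read_classifier_params",
    "write_classifier_params",
]


class CellClass(str, Enum):
    DSRED_POS = "dsred_pos"
    GFP_POS = "gfp_pos"
    DUAL = "dual"
    NEGATIVE = "negative"


# Optimized per-region thresholds for the original tissue
# (DAPI detection threshold, DsRed and GFP classification thresholds);
# these are scale-setting defaults and must be re-optimized per dataset.
REGION_THRESHOLD_DEFAULTS: dict[str, dict[str, float]] = {
    "cortex": {"dapi": 150, "dsred": 375, "gfp": 250},
    "hippocampus": {"dapi": 75, "dsred": 350, "gfp": 225},
    "thalamus": {"dapi": 150, "dsred": 325, "gfp": 200},
    "hypothalamus": {"dapi": 150, "dsred": 400, "gfp": 250},
}


@dataclass(frozen=True)
class ClassifierParams:
    """Per-region intensity thresholds for marker positivity."""

    region: str
    dsred_threshold: float
    gfp_threshold: float

    def __post_init__(self) -> None:
        if self.dsred_threshold < 0 or self.gfp_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    @classmethod
    def defaults_for(cls, region: str) -> "ClassifierParams":
        t = REGION_THRESHOLD_DEFAULTS[region]
        return cls(region, t["dsred"], t["gfp"])


def classify_cells(dets: Detections, params: ClassifierParams) -> Detections:
    """Assign one of the four classes to every detection (in a copy)."""
    for col in ("cell_mean_DsRed", "cell_mean_GFP"):
        if col not in dets.table.columns:
            raise ValueError(
                f"missing intensity measurements ({col}); run measure_intensities first"
            )
    out = dets.copy()
    dsred = out.table["cell_mean_DsRed"].to_numpy(dtype=float)
    gfp = out.table["cell_mean_GFP"].to_numpy(dtype=float)
    is_d = dsred >= params.dsred_threshold
    is_g = gfp >= params.gfp_threshold
    labels = np.where(
        is_d & is_g,
        CellClass.DUAL.value,
        np.where(
            is_d,
            CellClass.DSRED_POS.value,
            np.where(is_g, CellClass.GFP_POS.value, CellClass.NEGATIVE.value),
        ),
    )
    out.table["cell_class"] = labels
    return out


ClassCounts = namedtuple(
    "ClassCounts", ["n_total", "n_dsred", "n_gfp", "n_dual", "n_negative"]
)


def class_counts(dets: Detections) -> ClassCounts:
    """Count detections per class; the four classes sum to the total."""
    if len(dets) == 0:
        return ClassCounts(0, 0, 0, 0, 0)
    if "cell_class" not in dets.table.columns or dets.table["cell_class"].isna().any():
        raise ValueError("unclassified detections present; run classify_cells first")
    vc = dets.table["cell_class"].value_counts()
    counts = ClassCounts(
        n_total=int(len(dets)),
        n_dsred=int(vc.get(CellClass.DSRED_POS.value, 0)),
        n_gfp=int(vc.get(CellClass.GFP_POS.value, 0)),
        n_dual=int(vc.get(CellClass.DUAL.value, 0)),
        n_negative=int(vc.get(CellClass.NEGATIVE.value, 0)),
    )
    assert counts.n_total == counts.n_dsred + counts.n_gfp + counts.n_dual + counts.n_negative
    return counts


def write_classifier_params(params: dict[str, ClassifierParams], path) -> None:
    """Write per-region classifier thresholds as JSON keyed by region."""
    obj = {
        name: {"dsred_threshold": p.dsred_threshold, "gfp_threshold": p.gfp_threshold}
        for name, p in params.items()
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_classifier_params(path) -> dict[str, ClassifierParams]:
    obj = json.loads(Path(path).read_text())
    return {
        name: ClassifierParams(name, d["dsred_threshold"], d["gfp_threshold"])
        for name, d in obj.items()
    }
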