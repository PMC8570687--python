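"""Per-region quantification and cross-section summaries.

Counts classified detections whose nucleus centroid falls inside a
region's analyzed-tissue mask, converts them to percentages of total
detections and to densities per mm² of analyzed tissue area, and
summarizes across sections as mean ± sample SD.  Overall ("all regions")
percentages are computed per section over the union of analyzed regions
and then averaged across sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import CellClass, class_counts
from .containers import BinaryMask
from .detect import Detections

__all__ = ["RegionQuantification", "quantify_region", "summarize"]

_CLASS_KEYS = {
    CellClass.DSRED_POS.value: "dsred",
    CellClass.GFP_POS.value: "gfp",
    CellClass.DUAL.value: "dual",
    CellClass.NEGATIVE.value: "negative",
}


@dataclass
class RegionQuantification:
    """Counts, percentages and densities for one (section, region)."""

    section_id: str
    region: str
    area_mm2: float
    n_total: int
    n_dsred: int
    n_gfp: int
    n_dual: int
    n_negative: int
    no_cells: bool = False

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("area_mm2 must be positive")
        assert self.n_total == self.n_dsred + self.n_gfp + self.n_dual + self.n_negative

    def pct(self, key: str) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * getattr(self, f"n_{key}") / self.n_total

    def per_mm2(self, key: str) -> float:
        n = self.n_total if key == "total" else getattr(self, f"n_{key}")
        return n / self.area_mm2

    def as_dict(self) -> dict:
        d = {
            "section_id": self.section_id,
            "region": self.region,
            "area_mm2": self.area_mm2,
            "n_total": self.n_total,
            "n_dsred": self.n_dsred,
            "n_gfp": self.n_gfp,
            "n_dual": self.n_dual,
            "n_negative": self.n_negative,
        }
        for key in ("dsred", "gfp", "dual", "negative"):
            d[f"pct_{key}"] = self.pct(key)
        for key in ("total", "dsred", "gfp", "dual", "negative"):
            d[f"{key}_per_mm2"] = self.per_mm2(key)
        return d


def quantify_region(
    dets: Detections,
    region_mask: BinaryMask,
    section_id: str = "",
    region: str = "",
) -> RegionQuantification:
    """Quantify classified detections inside one region mask.

    A cell belongs to the region iff its nucleus centroid pixel is in the
    mask (cells straddling borders go to the region holding the
    centroid).  An empty mask is an error; a mask with zero detections is
    legitimate and flagged ``no_cells``.
    """
    if region_mask.is_empty():
        raise ValueError(f"region mask {region!r} is empty")
    ps = region_mask.pixel_size_um
    table = dets.table
    if len(table):
        if "cell_class" not in table.columns:
            raise ValueError("detections must be classified before quantification")
        rows = np.clip(
            (table["centroid_y_um"].to_numpy() / ps - 0.5).round().astype(int),
            0,
            region_mask.shape[0] - 1,
        )
        cols = np.clip(
            (table["centroid_x_um"].to_numpy() / ps - 0.5).round().astype(int),
            0,
            region_mask.shape[1] - 1,
        )
        inside = region_mask.data[rows, cols]
        classes = table["cell_class"].to_numpy()[inside]
    else:
        classes = np.array([], dtype=object)
    counts = {k: int((classes == c).sum()) for c, k in _CLASS_KEYS.items()}
    n_total = int(len(classes))
    return RegionQuantification(
        section_id=section_id,
        region=region,
        area_mm2=region_mask.area_mm2(),
        n_total=n_total,
        n_dsred=counts["dsred"],
        n_gfp=counts["gfp"],
        n_dual=counts["dual"],
        n_negative=counts["negative"],
        no_cells=n_total == 0,
    )


_SUMMARY_METRICS = [
    "area_mm2",
    "n_total",
    "pct_dsred",
    "pct_gfp",
    "pct_dual",
    "pct_negative",
    "total_per_mm2",
    "dsred_per_mm2",
    "gfp_per_mm2",
]


def summarize(
    quants: Sequence[RegionQuantification],
    metrics: Iterable[str] = _SUMMARY_METRICS,
) -> pd.DataFrame:
    """Mean ± sample SD of each metric per region and over all regions.

    Returns a tidy table with columns (region, metric, mean, sd, n); the
    ``all regions`` rows pool counts over the analyzed regions within
    each section before averaging across sections.  With a single
    section the SD is reported as NaN.
    """
    if not quants:
        raise ValueError("no quantifications to summarize")
    df = pd.DataFrame([q.as_dict() for q in quants])
    metrics = list(metrics)

    rows = []
    for region, sub in df.groupby("region"):
        for m in metrics:
            rows.append(
                {
                    "region": region,
                    "metric": m,
                    "mean": sub[m].mean(),
                    "sd": sub[m].std(ddof=1),
                    "n": len(sub),
                }
            )

    # pooled across regions, per section first
    pooled_rows = []
    for section, sub in df.groupby("section_id"):
        pooled = {
            "section_id": section,
            "area_mm2": sub["area_mm2"].sum(),
            "n_total": sub["n_total"].sum(),
        }
        for key in ("dsred", "gfp", "dual", "negative"):
            n = sub[f"n_{key}"].sum()
            pooled[f"pct_{key}"] = 100.0 * n / pooled["n_total"] if pooled["n_total"] else 0.0
            pooled[f"{key}_per_mm2"] = n / pooled["area_mm2"]
        pooled["total_per_mm2"] = pooled["n_total"] / pooled["area_mm2"]
        pooled_rows.append(pooled)
    pooled_df = pd.DataFrame(pooled_rows)
    for m in metrics:
        if m not in pooled_df.columns:
            continue
        rows.append(
            {
                "region": "all regions",
                "metric": m,
                "mean": pooled_df[m].mean(),
                "sd": pooled_df[m].std(ddof=1),
                "n": len(pooled_df),
            }
        )
    return pd.DataFrame(rows, columns=["region", "metric", "mean", "sd", "n"])
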