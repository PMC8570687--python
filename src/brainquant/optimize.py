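"""Grid-sweep optimization of detection/classification thresholds.

A swept parameter (the DAPI detection threshold, or a DsRed/GFP
classification threshold) is evaluated over a fixed grid against manual
counts in small test annotations.  Each grid value is scored by the
percent difference

    %difference = ((Ac - Mc) / Mc) * 100

between the automated count Ac and the manual count Mc, summarized as
mean +/- sample SD across annotations.  The optimum is the grid value
with the smallest absolute mean, ties broken by smaller SD, then by a
preference for undercounting (mean <= 0), then by the larger threshold.

The sweep is exposed as a model object: build a :class:`ThresholdSweep`
from a :class:`SweepSpec` plus the images, call :meth:`fit`, and read the
selected optimum and diagnostics off the returned :class:`SweepResult`.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .containers import BinaryMask, SectionImage
from .annotations import rasterize_geometry
from .detect import DetectionParams, detect_nuclei, expand_cells, measure_intensities

__all__ = [
    "percent_difference",
    "SweepAnnotation",
    "SweepSpec",
    "ThresholdSweep",
    "SweepResult",
    "select_optimum",
    "pooled_region_optimum",
    "Optimum",
]

DETECTION_THRESHOLD = "detection.threshold"
CLASSIFIER_DSRED = "classifier.dsred_threshold"
CLASSIFIER_GFP = "classifier.gfp_threshold"

_CHANNEL_FOR = {CLASSIFIER_DSRED: "DsRed", CLASSIFIER_GFP: "GFP"}


def percent_difference(ac: float, mc: float) -> float:
    """((Ac - Mc) / Mc) x 100; positive means overcounting."""
    if mc <= 0:
        raise ValueError("manual count must be positive for a percent difference")
    return (ac - mc) / mc * 100.0


@dataclass(frozen=True)
class SweepAnnotation:
    """One scored test rectangle with its manual ground-truth count."""

    section_id: str
    region: str
    rectangle: Polygon  # pixel coordinates on its section
    manual_count: int


@dataclass(frozen=True)
class SweepSpec:
    """What to sweep, over which grid, scored on which annotations."""

    parameter: str  # one of DETECTION_THRESHOLD / CLASSIFIER_DSRED / CLASSIFIER_GFP
    start: float
    stop: float
    step: float
    annotations: tuple[SweepAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if len(self.grid) == 0:
            raise ValueError("empty sweep grid")
        known = (DETECTION_THRESHOLD, CLASSIFIER_DSRED, CLASSIFIER_GFP)
        if self.parameter not in known:
            raise ValueError(f"unknown parameter {self.parameter!r}; expected one of {known}")

    @property
    def grid(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def channel(self) -> str | None:
        return _CHANNEL_FOR.get(self.parameter)


Optimum = namedtuple("Optimum", ["value", "mean", "sd", "ranking"])


def _rank(curve: pd.DataFrame) -> pd.DataFrame:
    """Order candidate grid values by the selection rule (best first)."""
    scored = curve.dropna(subset=["mean"]).copy()
    if scored.empty:
        raise ValueError("no scored grid values to select from")
    scored["abs_mean"] = scored["mean"].abs().round(9)
    scored["sd_key"] = scored["sd"].fillna(0.0).round(9)
    scored["overcount"] = (scored["mean"] > 1e-9).astype(int)
    scored = scored.sort_values(
        ["abs_mean", "sd_key", "overcount", "value"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    return scored.drop(columns=["abs_mean", "sd_key", "overcount"])


def select_optimum(curve: pd.DataFrame) -> Optimum:
    """Select the optimal grid value from a (value, mean, sd) curve.

    Lexicographic rule: smallest ``|mean|``; ties by smallest SD; ties by
    preferring ``mean <= 0`` (undercounting); ties by the larger value.
    The full ranking is returned for audit.
    """
    ranking = _rank(curve)
    best = ranking.iloc[0]
    return Optimum(
        value=float(best["value"]),
        mean=float(best["mean"]),
        sd=float(best["sd"]) if pd.notna(best["sd"]) else float("nan"),
        ranking=ranking.reset_index(drop=True),
    )


def pooled_region_optimum(curves: Mapping[str, pd.DataFrame]) -> Optimum:
    """One threshold for several sub-regions: minimize the worst case.

    Selects the grid value minimizing the maximum ``|mean %difference|``
    across sub-region curves sharing a common grid (the way one threshold
    is chosen for a compound region whose sub-fields individually prefer
    different values); ties resolved as in :func:`select_optimum`.
    """
    if len(curves) < 2:
        raise ValueError("need at least two sub-region curves")
    frames = list(curves.values())
    grid = frames[0]["value"].to_numpy()
    for f in frames[1:]:
        if not np.array_equal(f["value"].to_numpy(), grid):
            raise ValueError("sub-region sweeps must share a common grid")
    stacked = pd.concat(frames, keys=list(curves), names=["subregion"]).reset_index(
        level=0
    )
    agg = stacked.groupby("value").agg(
        worst=("mean", lambda m: np.max(np.abs(m))),
        mean=("mean", "mean"),
        sd=("sd", "max"),
    )
    pooled = pd.DataFrame(
        {
            "value": agg.index.to_numpy(dtype=float),
            # the worst-case |mean| drives selection; signed pooled mean is
            # kept so the undercount preference still applies on exact ties
            "mean": np.where(agg["mean"] <= 0, -agg["worst"], agg["worst"]),
            "sd": agg["sd"].to_numpy(),
        }
    )
    opt = select_optimum(pooled)
    return Optimum(opt.value, float(agg.loc[opt.value, "worst"]), opt.sd, opt.ranking)


class ThresholdSweep:
    """Model object: a grid sweep of one parameter against manual counts.

    Parameters
    ----------
    spec
        The sweep specification (parameter, grid, annotations).
    sections
        Mapping from section id to its SectionImage.
    masks
        Optional mapping from section id to the analyzed-tissue mask
        (tissue minus vessels); annotations are intersected with it.
    detection_params
        Baseline detection parameters, either one set for all regions or
        a mapping from region name to parameters (so classification
        sweeps can run at each region's optimized DAPI threshold).
    crop_pad_px
        Margin kept around each annotation crop so smoothing and cell
        expansion are unaffected by the crop boundary.
    """

    def __init__(
        self,
        spec: SweepSpec,
        sections: Mapping[str, SectionImage],
        masks: Mapping[str, BinaryMask] | None = None,
        detection_params: DetectionParams | Mapping[str, DetectionParams] | None = None,
        crop_pad_px: int = 16,
    ) -> None:
        self.spec = spec
        self.sections = dict(sections)
        self.masks = dict(masks) if masks else None
        self.detection_params = detection_params or DetectionParams()
        self.crop_pad_px = int(crop_pad_px)
        for a in spec.annotations:
            if a.section_id not in self.sections:
                raise KeyError(f"annotation references unknown section {a.section_id!r}")

    def _params_for(self, region: str) -> DetectionParams:
        if isinstance(self.detection_params, DetectionParams):
            return self.detection_params
        return self.detection_params[region]

    def _annotation_context(self, a: SweepAnnotation):
        """Crop the section around one annotation; build its within-mask."""
        img = self.sections[a.section_id]
        minx, miny, maxx, maxy = a.rectangle.bounds
        pad = self.crop_pad_px
        r0 = max(int(np.floor(miny)) - pad, 0)
        r1 = min(int(np.ceil(maxy)) + pad, img.height)
        c0 = max(int(np.floor(minx)) - pad, 0)
        c1 = min(int(np.ceil(maxx)) + pad, img.width)
        crop = img.crop(r0, r1, c0, c1)
        from shapely.affinity import translate

        rect_local = translate(a.rectangle, xoff=-c0, yoff=-r0)
        within = rasterize_geometry(rect_local, crop.shape)
        if self.masks is not None and a.section_id in self.masks:
            within &= self.masks[a.section_id].data[r0:r1, c0:c1]
        return crop, BinaryMask(within, img.pixel_size_um)

    def fit(self) -> "SweepResult":
        """Run the sweep and score every grid value. Returns the results."""
        spec = self.spec
        records: list[dict] = []
        for a in spec.annotations:
            if a.manual_count <= 0:
                warnings.warn(
                    f"annotation ({a.section_id}, {a.region}) has no manual count; excluded",
                    stacklevel=2,
                )
                continue
            crop, within = self._annotation_context(a)
            base = self._params_for(a.region)
            if spec.parameter == DETECTION_THRESHOLD:
                for value in spec.grid:
                    try:
                        dets = detect_nuclei(crop, within, base.replace(threshold=value))
                        ac: float = float(len(dets))
                    except Exception as exc:  # annotation fails at this value
                        warnings.warn(
                            f"detection failed at {value} on ({a.section_id}, "
                            f"{a.region}): {exc}",
                            stacklevel=2,
                        )
                        ac = np.nan
                    records.append(self._record(a, value, ac))
            else:
                # detections are independent of a classification threshold:
                # detect once, then count cells above each grid value
                channel = spec.channel
                try:
                    dets = detect_nuclei(crop, within, base)
                    dets = expand_cells(dets, base.cell_expansion_um, within)
                    dets = measure_intensities(dets, crop)
                    means = dets.table[f"cell_mean_{channel}"].to_numpy(dtype=float)
                except Exception as exc:
                    warnings.warn(
                        f"detection failed on ({a.section_id}, {a.region}): {exc}",
                        stacklevel=2,
                    )
                    means = None
                for value in spec.grid:
                    ac = float((means >= value).sum()) if means is not None else np.nan
                    records.append(self._record(a, value, ac))
        return SweepResult(spec, pd.DataFrame.from_records(records))

    def _record(self, a: SweepAnnotation, value: float, ac: float) -> dict:
        pct = (
            percent_difference(ac, a.manual_count) if np.isfinite(ac) else np.nan
        )
        return {
            "value": float(value),
            "section_id": a.section_id,
            "region": a.region,
            "ac": ac,
            "mc": a.manual_count,
            "pct_diff": pct,
        }


class SweepResult:
    """Per-grid-value scores of a threshold sweep, plus the selection.

    ``records`` is a long-form table with one row per (grid value,
    annotation): automated count, manual count and percent difference.
    """

    def __init__(self, spec: SweepSpec, records: pd.DataFrame) -> None:
        self.spec = spec
        self.records = records

    @property
    def n_annotations(self) -> int:
        if self.records.empty:
            return 0
        return self.records.groupby(["section_id", "region"]).ngroups

    def curve(self, region: str | None = None) -> pd.DataFrame:
        """Mean +/- sample SD of %difference per grid value.

        The mean at a grid value is reported only when every annotation
        produced a score there.
        """
        rec = self.records
        if region is not None:
            rec = rec[rec["region"] == region]
        if rec.empty:
            raise ValueError("no sweep records" + (f" for region {region!r}" if region else ""))
        n_expected = rec.groupby(["section_id", "region"]).ngroups
        g = rec.groupby("value")["pct_diff"]
        out = pd.DataFrame(
            {
                "value": sorted(rec["value"].unique()),
            }
        )
        stats = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        out = out.merge(stats, left_on="value", right_index=True, how="left")
        incomplete = out["n"] < n_expected
        out.loc[incomplete, ["mean", "sd"]] = np.nan
        return out

    def select_optimum(self, region: str | None = None) -> Optimum:
        return select_optimum(self.curve(region))

    def optimum_by_region(self) -> dict[str, Optimum]:
        regions = sorted(self.records["region"].unique())
        return {r: self.select_optimum(r) for r in regions}

    def summary(self) -> str:
        """Human-readable summary of the sweep and its selected optima."""
        lines = [
            f"Threshold sweep: {self.spec.parameter}",
            f"  grid: {self.spec.start} .. {self.spec.stop} step {self.spec.step}",
            f"  annotations scored: {self.n_annotations}",
            "",
            f"  {'region':<16}{'optimum':>9}{'mean %diff':>12}{'SD':>9}",
        ]
        for region, opt in self.optimum_by_region().items():
            sd = f"{opt.sd:.2f}" if np.isfinite(opt.sd) else "NA"
            lines.append(f"  {region:<16}{opt.value:>9.0f}{opt.mean:>12.2f}{sd:>9}")
        pooled = self.select_optimum()
        sd = f"{pooled.sd:.2f}" if np.isfinite(pooled.sd) else "NA"
        lines.append(f"  {'(all pooled)':<16}{pooled.value:>9.0f}{pooled.mean:>12.2f}{sd:>9}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def plot(self, region: str | None = None, ax=None):
        """%difference curve (mean +/- SD) with the zero line, Fig.-style."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve(region)
        ax.axhline(0.0, ls=":", color="k", lw=1)
        ax.errorbar(c["value"], c["mean"], yerr=c["sd"], fmt="o-", ms=3, capsize=2)
        ax.set_xlabel(self.spec.parameter)
        ax.set_ylabel("% difference vs manual counts")
        if region:
            ax.set_title(region)
        return ax
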