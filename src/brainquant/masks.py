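"""Tissue-area and large-vessel pixel classification and mask algebra.

The tissue classifier thresholds the Gaussian-smoothed average of all
channels, fills small holes, drops small components, erodes the boundary
inward (to escape the brighter tissue edge) and removes leftover
fragments.  The vessel classifier applies the same machinery to the DsRed
channel with a high threshold, picking up large DsRed-bright vessels
(vascular smooth muscle) that must not be counted as pericyte territory.
Vessels are then subtracted from tissue, and the result is intersected
with the named brain-region annotations.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .annotations import AnnotationSet, rasterize_geometry
from .containers import BinaryMask, SectionImage

AVERAGE = "average"

__all__ = [
    "MaskParams",
    "detect_tissue",
    "detect_vessels",
    "subtract",
    "intersect_regions",
    "AVERAGE",
]


@dataclass(frozen=True)
class MaskParams:
    """Parameters for one pixel-classifier mask.

    Defaults are the tissue classifier's; use :meth:`vessels` for the
    large-vessel classifier.  Thresholding is inclusive (``>=``).
    """

    channels_used: str = AVERAGE  # "average" or a single channel name
    smoothing_sigma_px: float = 2.0
    threshold: float = 50.0
    min_area_um2: float = 1_000_000.0
    min_hole_um2: float = 1000.0
    erode_um: float = 40.0
    min_fragment_um2: float = 10_000.0

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0:
            raise ValueError("sigma must be >= 0")
        for f in ("min_area_um2", "min_hole_um2", "erode_um", "min_fragment_um2"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @classmethod
    def tissue(cls, **kwargs) -> "MaskParams":
        return cls(**kwargs)

    @classmethod
    def vessels(cls, **kwargs) -> "MaskParams":
        base = dict(
            channels_used="DsRed",
            smoothing_sigma_px=2.0,
            threshold=400.0,
            min_area_um2=150.0,
            min_hole_um2=1000.0,
            erode_um=0.0,
            min_fragment_um2=0.0,
        )
        base.update(kwargs)
        return cls(**base)

    def replace(self, **kwargs) -> "MaskParams":
        return dataclasses.replace(self, **kwargs)


def remove_small_components(binary: np.ndarray, min_area_px: float) -> np.ndarray:
    """Drop connected components with pixel area strictly below the limit."""
    if min_area_px <= 1 or not binary.any():
        return binary
    lab, n = ndi.label(binary)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[lab]


def fill_small_holes(binary: np.ndarray, max_area_px: float) -> np.ndarray:
    """Fill background components strictly inside the foreground whose
    pixel area is strictly below the limit."""
    if max_area_px <= 0 or not binary.any():
        return binary
    lab, n = ndi.label(~binary)
    if n == 0:
        return binary
    sizes = np.bincount(lab.ravel())
    fill = sizes < max_area_px
    fill[0] = False
    # background touching the image border is not a hole
    border = np.unique(
        np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    )
    fill[border] = False
    return binary | fill[lab]


def _erode_by_disc(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Exact Euclidean erosion by a disc of the given pixel radius."""
    if radius_px <= 0 or not mask.any():
        return mask
    return ndi.distance_transform_edt(mask) > radius_px


def _classify_pixels(raster: np.ndarray, p: MaskParams, pixel_size_um: float) -> np.ndarray:
    """Shared classifier chain: smooth, threshold, clean up."""
    px_area = pixel_size_um**2
    sm = ndi.gaussian_filter(raster.astype(np.float64), p.smoothing_sigma_px)
    binary = sm >= p.threshold
    if p.min_hole_um2 > 0:
        binary = fill_small_holes(binary, p.min_hole_um2 / px_area)
    if p.min_area_um2 > 0:
        binary = remove_small_components(binary, p.min_area_um2 / px_area)
    if p.erode_um > 0:
        binary = _erode_by_disc(binary, int(round(p.erode_um / pixel_size_um)))
    if p.min_fragment_um2 > 0:
        binary = remove_small_components(binary, p.min_fragment_um2 / px_area)
    return binary


def detect_tissue(img: SectionImage, p: MaskParams | None = None) -> BinaryMask:
    """Detect the tissue area from the average of all channels."""
    p = p or MaskParams.tissue()
    if p.channels_used != AVERAGE:
        raise ValueError("tissue detection uses the average of all channels")
    binary = _classify_pixels(img.average_channel(), p, img.pixel_size_um)
    if not binary.any():
        warnings.warn("tissue mask is empty after filtering", stacklevel=2)
    return BinaryMask(binary, img.pixel_size_um)


def detect_vessels(img: SectionImage, p: MaskParams | None = None) -> BinaryMask:
    """Detect large bright vessels on a single (DsRed) channel."""
    p = p or MaskParams.vessels()
    if p.channels_used == AVERAGE:
        raise ValueError("vessel detection uses a single channel (DsRed)")
    binary = _classify_pixels(img.channel(p.channels_used), p, img.pixel_size_um)
    return BinaryMask(binary, img.pixel_size_um)


def subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixels of ``a`` not in ``b`` (tissue minus vessels)."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.data & ~b.data, a.pixel_size_um)


def intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.data & b.data, a.pixel_size_um)


def intersect_regions(
    tissue: BinaryMask,
    regions: AnnotationSet,
    names: list[str] | None = None,
) -> dict[str, BinaryMask]:
    """Intersect the (vessel-subtracted) tissue mask with region polygons."""
    region_annots = {a.name: a for a in regions.by_role("region")}
    if names is None:
        names = list(region_annots)
    out: dict[str, BinaryMask] = {}
    for name in names:
        if name not in region_annots:
            raise KeyError(f"unknown region {name!r}; have {sorted(region_annots)}")
        poly_mask = rasterize_geometry(region_annots[name].geometry, tissue.shape)
        out[name] = BinaryMask(tissue.data & poly_mask, tissue.pixel_size_um)
    return out
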