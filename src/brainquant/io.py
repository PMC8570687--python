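"""Readers and writers for the formats the pipeline touches.

Multi-channel TIFF images (pixel size in the TIFF resolution tags and a
JSON sidecar), GeoJSON annotation sets, and CSV measurement tables.
Readers and writers are exact inverses on their own output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .annotations import AnnotationSet
from .containers import SectionImage

DEFAULT_CHANNELS = ("DAPI", "DsRed", "GFP")

__all__ = [
    "read_section",
    "write_section",
    "read_annotations",
    "write_annotations",
    "write_measurements",
    "DEFAULT_CHANNELS",
]


def write_section(img: SectionImage, path: str | Path) -> Path:
    """Write a SectionImage as a multi-channel TIFF.

    Pixel size is stored in the X/Y resolution tags (pixels per
    centimetre) and, with the channel names, in a ``.json`` sidecar next
    to the image.
    """
    path = Path(path)
    px_per_cm = 1e4 / img.pixel_size_um
    tifffile.imwrite(
        path,
        img.pixels,
        photometric="minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"axes": "CYX"},
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "channel_names": list(img.channel_names),
                "pixel_size_um": img.pixel_size_um,
            }
        )
    )
    return path


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is None or unit is None:
        return None
    num, den = res.value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = getattr(unit.value, "value", unit.value)  # enum or int
    if unit == 3:  # centimetre
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    return None


def read_section(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> SectionImage:
    """Read a multi-channel (or multi-page) TIFF as a SectionImage.

    Channels are named from the sidecar written by :func:`write_section`
    when present, else from ``channel_names``, else from the default
    DAPI/DsRed/GFP order.  Pixel size comes from the sidecar or the TIFF
    resolution tags unless overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        tag_pixel_size = _pixel_size_from_tags(tif)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D multi-channel image")
    # channel axis may come last for some writers; channels are the short axis
    if pixels.shape[0] > pixels.shape[2]:
        pixels = np.moveaxis(pixels, 2, 0)
    if pixels.shape[0] < 3:
        raise ValueError(
            f"{path}: needs >=3 channels (DAPI, DsRed, GFP), got {pixels.shape[0]}"
        )

    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    names = channel_names or meta.get("channel_names")
    if names is None:
        names = list(DEFAULT_CHANNELS) + [
            f"channel-{i}" for i in range(3, pixels.shape[0])
        ]
    pixel_size = pixel_size_override or meta.get("pixel_size_um") or tag_pixel_size
    if pixel_size is None:
        raise ValueError(f"{path}: no pixel size in tags or sidecar; pass an override")
    return SectionImage(pixels, tuple(names), float(pixel_size), source_path=path)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of annotations."""
    return AnnotationSet.read(path)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> Path:
    """Write an AnnotationSet as a GeoJSON FeatureCollection."""
    annotations.write(path)
    return Path(path)


MEASUREMENT_COLUMNS = [
    "section_id",
    "region",
    "area_mm2",
    "n_total",
    "n_dsred",
    "n_gfp",
    "n_dual",
    "n_negative",
    "pct_dsred",
    "pct_gfp",
    "pct_dual",
    "pct_negative",
    "total_per_mm2",
    "dsred_per_mm2",
    "gfp_per_mm2",
    "dual_per_mm2",
    "negative_per_mm2",
]


def write_measurements(quantifications: Iterable, path: str | Path) -> Path:
    """Write per-(section, region) quantifications as a CSV table."""
    rows = [q.as_dict() for q in quantifications]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)
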