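"""Named polygon annotations and point counts, with GeoJSON round-trip.

Annotations carry pixel coordinates (origin top-left, y down, 0-based).
GeoJSON features follow the whole-slide-annotation dialect: polygon
features carry ``properties.classification = {"name": ...}`` and
``properties.role``; point features used for manual counts carry
``properties.channel``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import shapely
from shapely.geometry import MultiPoint, MultiPolygon, Polygon, mapping, shape
from shapely.affinity import scale as _scale

ROLES = ("region", "tissue", "vessels", "test-rect", "detection")

__all__ = ["Annotation", "PointAnnotation", "AnnotationSet", "rasterize_geometry"]


@dataclass
class Annotation:
    """One named, possibly multi-part polygon with a pipeline role."""

    name: str
    geometry: Polygon | MultiPolygon
    role: str = "region"

    def __post_init__(self) -> None:
        if self.geometry.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unsupported geometry {self.geometry.geom_type}")
        if not self.geometry.is_valid:
            raise ValueError(f"annotation {self.name!r} has invalid geometry")

    def to_um(self, pixel_size_um: float) -> Polygon | MultiPolygon:
        """Geometry scaled from pixel to micrometre coordinates."""
        return _scale(
            self.geometry, xfact=pixel_size_um, yfact=pixel_size_um, origin=(0, 0)
        )


@dataclass
class PointAnnotation:
    """Manually placed count points for one channel (pixel coordinates)."""

    channel: str
    xy: np.ndarray  # (n, 2) array of (x, y)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)


class AnnotationSet:
    """A collection of named polygon annotations plus optional point lists."""

    def __init__(
        self,
        annotations: Iterable[Annotation] = (),
        points: Iterable[PointAnnotation] = (),
    ) -> None:
        self.annotations: list[Annotation] = list(annotations)
        self.points: list[PointAnnotation] = list(points)
        self._check_unique_names()

    def _check_unique_names(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a in self.annotations:
            key = (a.role, a.name)
            if key in seen:
                raise ValueError(f"duplicate annotation {a.name!r} for role {a.role!r}")
            seen.add(key)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)

    def add(self, annotation: Annotation) -> None:
        self.annotations.append(annotation)
        self._check_unique_names()

    def by_role(self, role: str) -> list[Annotation]:
        return [a for a in self.annotations if a.role == role]

    def get(self, name: str, role: str | None = None) -> Annotation:
        for a in self.annotations:
            if a.name == name and (role is None or a.role == role):
                return a
        raise KeyError(f"no annotation named {name!r}" + (f" with role {role!r}" if role else ""))

    def names(self, role: str | None = None) -> list[str]:
        return [a.name for a in self.annotations if role is None or a.role == role]

    # -- GeoJSON -----------------------------------------------------------

    def to_geojson(self) -> dict:
        features = []
        for a in self.annotations:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(a.geometry),
                    "properties": {
                        "classification": {"name": a.name},
                        "role": a.role,
                    },
                }
            )
        for p in self.points:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(MultiPoint(p.xy)),
                    "properties": {"channel": p.channel},
                }
            )
        return {"type": "FeatureCollection", "features": features}

    @classmethod
    def from_geojson(cls, obj: dict) -> "AnnotationSet":
        if obj.get("type") != "FeatureCollection":
            raise ValueError("expected a GeoJSON FeatureCollection")
        annotations: list[Annotation] = []
        points: list[PointAnnotation] = []
        for i, feat in enumerate(obj.get("features", [])):
            try:
                geom = shape(feat["geometry"])
            except Exception as exc:  # malformed geometry dict
                raise ValueError(f"feature {i}: unreadable geometry ({exc})") from exc
            props = feat.get("properties") or {}
            if geom.geom_type in ("Polygon", "MultiPolygon"):
                if not geom.is_valid:
                    raise ValueError(f"feature {i}: invalid polygon geometry")
                name = (props.get("classification") or {}).get("name") or props.get(
                    "name", f"annotation-{i}"
                )
                role = props.get("role", "region")
                annotations.append(Annotation(name, geom, role))
            elif geom.geom_type in ("Point", "MultiPoint"):
                coords = shapely.get_coordinates(geom)
                points.append(PointAnnotation(props.get("channel", ""), coords))
            else:
                raise ValueError(f"feature {i}: unsupported geometry {geom.geom_type}")
        return cls(annotations, points)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_geojson(), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "AnnotationSet":
        return cls.from_geojson(json.loads(Path(path).read_text()))


def rasterize_geometry(
    geometry: Polygon | MultiPolygon, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polygon (pixel coordinates) onto a boolean grid.

    A pixel belongs to the polygon iff its center ``(j + 0.5, i + 0.5)``
    is strictly contained, so polygons that share only a boundary
    rasterize to disjoint masks.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = geometry.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, w)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, h)
    if c1 <= c0 or r1 <= r0:
        return out
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xx, yy = np.meshgrid(cols + 0.5, rows + 0.5)
    inside = shapely.contains_xy(geometry, xx.ravel(), yy.ravel())
    out[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return out
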