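"""Synthetic multi-channel brain-section generator with known ground truth.

Emulates, at desk scale, the features of scanned coronal sections that the
pipeline has to cope with: DAPI-stained nuclei at region-dependent
densities, DsRed-positive pericyte somata attached to a sparse capillary
network plus occasional large bright vessels (vascular smooth muscle),
GFP-positive microglia with thin ramified processes, region-dependent
background, brighter tissue edges, and a configurable fraction of dim
(out-of-focus-like) nuclei and deliberately touching nucleus pairs.

Morphology is cosmetic — downstream classification is intensity-only — but
intensities are drawn so that positive and negative cells are separated by
a known gap on a 16-bit-like scale, with per-cell foreground draws clipped
to two standard deviations so the separating gap is guaranteed rather than
merely probable.
"""

from __future__ import annotations

import dataclasses
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from shapely.affinity import scale as _scale
from shapely.geometry import MultiPolygon, Point, Polygon, box

from .annotations import Annotation, AnnotationSet, rasterize_geometry
from .containers import SectionImage

__all__ = [
    "SectionConfig",
    "GroundTruthCell",
    "CountTriple",
    "generate_section",
    "generate_test_annotations",
    "ground_truth_counts",
    "write_ground_truth",
    "read_ground_truth",
    "default_regions",
]

CountTriple = namedtuple("CountTriple", ["total", "dsred", "gfp"])

PERICYTE = "pericyte"
MICROGLIA = "microglia"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ClassIntensity:
    """Per-cell foreground intensity model: draws are clipped to mean +/- 2 SD."""

    mean: float
    sd: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        v = rng.normal(self.mean, self.sd, size=n)
        return np.clip(v, self.mean - 2 * self.sd, self.mean + 2 * self.sd)

    @property
    def minimum(self) -> float:
        return self.mean - 2 * self.sd


@dataclass(frozen=True)
class ChannelBackground:
    """Additive background level outside tissue, inside tissue, per region."""

    outside: float
    tissue: float
    by_region: Mapping[str, float] = field(default_factory=dict)

    def region_level(self, name: str) -> float:
        return float(self.by_region.get(name, self.tissue))


def default_regions(width_um: float, height_um: float) -> tuple[tuple[str, Polygon], ...]:
    """Four rectangular brain regions laid out inside the tissue area.

    Regions keep at least 160 um clearance from the image border so they
    stay clear of the brightened tissue edge (tissue margin plus the
    edge-ramp band) at any section size.
    """
    mx = max(0.08 * width_um, 160.0)
    my = max(0.08 * height_um, 160.0)
    sx = width_um - 2 * mx
    sy = height_um - 2 * my

    def bx(fx0, fy0, fx1, fy1):
        return box(mx + fx0 * sx, my + fy0 * sy, mx + fx1 * sx, my + fy1 * sy)

    return (
        ("cortex", bx(0.0, 0.0, 1.0, 0.30)),
        ("hippocampus", bx(0.0, 0.35, 1.0, 0.65)),
        ("thalamus", bx(0.0, 0.70, 0.48, 1.0)),
        ("hypothalamus", bx(0.52, 0.70, 1.0, 1.0)),
    )


# Default class fractions follow the regional proportions the pipeline is
# expected to recover: pericytes enriched in thalamus, microglia in cortex.
DEFAULT_PERICYTE_FRACTION = {
    "cortex": 0.0268,
    "hippocampus": 0.0177,
    "thalamus": 0.0620,
    "hypothalamus": 0.0237,
}
DEFAULT_MICROGLIA_FRACTION = {
    "cortex": 0.0554,
    "hippocampus": 0.0405,
    "thalamus": 0.0399,
    "hypothalamus": 0.0323,
}
# Densities put ~50-150 nuclei into one 300 x 200 um test annotation.
DEFAULT_NUCLEUS_DENSITY = {
    "cortex": 1500.0,
    "hippocampus": 2100.0,
    "thalamus": 1250.0,
    "hypothalamus": 1400.0,
}


@dataclass
class SectionConfig:
    """Full parameterization of one synthetic section.

    All geometry is in micrometres; intensities are arbitrary
    16-bit-like counts in [0, 65535] on the scale the classification
    threshold grids expect.
    """

    width_um: float = 2000.0
    height_um: float = 2000.0
    pixel_size_um: float = 1.0
    regions: Sequence[tuple[str, Polygon]] | None = None
    nucleus_density: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NUCLEUS_DENSITY)
    )
    pericyte_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PERICYTE_FRACTION)
    )
    microglia_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MICROGLIA_FRACTION)
    )
    nucleus_radius_um: float = 3.5
    nucleus_radius_sd_um: float = 0.5
    # foreground intensity per class and channel
    dapi_nucleus: ClassIntensity = ClassIntensity(550.0, 80.0)
    # pericyte somata stay below the large-vessel pixel classifier's reach:
    # bright enough to straddle the DsRed threshold grid as cell means, but
    # small and dim enough that no soma yields >=150 um2 above 400 counts
    dsred_soma: ClassIntensity = ClassIntensity(460.0, 40.0)
    gfp_soma: ClassIntensity = ClassIntensity(420.0, 50.0)
    background: Mapping[str, ChannelBackground] = field(
        default_factory=lambda: {
            "DAPI": ChannelBackground(5.0, 60.0),
            "DsRed": ChannelBackground(5.0, 80.0),
            "GFP": ChannelBackground(5.0, 45.0),
        }
    )
    edge_brightening_amplitude: float = 120.0
    edge_brightening_width_um: float = 60.0
    capillaries_per_mm2: float = 12.0
    capillary_intensity: float = 180.0
    capillary_width_um: float = 2.0
    large_vessel_count: int = 2
    large_vessel_width_um: float = 25.0
    large_vessel_intensity: float = 700.0
    dim_fraction: float = 0.05
    dim_factor: float = 0.5
    touching_fraction: float = 0.05
    min_separation_factor: float = 1.6
    # additive clearance: rings of non-touching neighbors can never reach
    # a soma interior (soma extent <= r+3.8, ring extent <= r+2.5)
    min_clearance_um: float = 6.5
    noise_sd: float = 12.0
    tissue_margin_um: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions is None:
            self.regions = default_regions(self.width_um, self.height_um)
        self.validate()

    def validate(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        shape = self.shape_px
        if max(shape) > 4096:
            raise ValueError(f"section too large for desk scale: {shape} px")
        for name, _ in self.regions:
            d = float(self.nucleus_density.get(name, 0.0))
            if d < 0:
                raise ValueError(f"negative nucleus density for {name!r}")
            pf = float(self.pericyte_fraction.get(name, 0.0))
            mf = float(self.microglia_fraction.get(name, 0.0))
            if not (0 <= pf <= 1 and 0 <= mf <= 1):
                raise ValueError(f"class fractions for {name!r} must be in [0, 1]")
            if pf + mf > 1:
                raise ValueError(
                    f"pericyte + microglia fraction exceeds 1 for {name!r}"
                )
        names = [n for n, _ in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for i, (na, ga) in enumerate(self.regions):
            for nb, gb in list(self.regions)[i + 1 :]:
                if ga.intersection(gb).area > 1e-9:
                    raise ValueError(f"regions {na!r} and {nb!r} overlap")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.height_um / self.pixel_size_um)),
            int(round(self.width_um / self.pixel_size_um)),
        )

    @property
    def tissue_polygon_um(self) -> Polygon:
        m = self.tissue_margin_um
        return box(m, m, self.width_um - m, self.height_um - m)

    def replace(self, **kwargs) -> "SectionConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruthCell:
    """One simulated cell: position, size, true class, rendered intensities."""

    id: int
    x_um: float
    y_um: float
    radius_um: float
    cell_class: str
    region: str
    dim: bool = False
    dapi_peak: float = 0.0
    dsred_value: float = 0.0
    gfp_value: float = 0.0


# --------------------------------------------------------------------------
# placement


def _sample_positions(
    rng: np.random.Generator,
    polygon: Polygon,
    n: int,
    radii_mean: float,
    radii_sd: float,
    min_sep_factor: float,
    min_clearance: float,
    touching_fraction: float,
    region_name: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place n nuclei in a polygon with a minimum center-to-center distance.

    A configurable fraction of nuclei is instead attached to the previous
    nucleus as a deliberately touching pair (to exercise watershed
    splitting).  Returns (xy, radii, touching_flag).
    """
    minx, miny, maxx, maxy = polygon.bounds
    placed_xy: list[tuple[float, float]] = []
    radii: list[float] = []
    touching: list[bool] = []
    attempts = 0
    limit = 400 * n + 400
    while len(placed_xy) < n:
        if attempts > limit:
            raise RuntimeError(
                f"nucleus placement failed in region {region_name!r} "
                f"after {attempts} attempts ({len(placed_xy)}/{n} placed); "
                "density too high for the region area"
            )
        attempts += 1
        r = float(
            np.clip(
                rng.normal(radii_mean, radii_sd),
                max(1.5, radii_mean - 2 * radii_sd),
                radii_mean + 2 * radii_sd,
            )
        )
        make_pair = placed_xy and rng.random() < touching_fraction
        if make_pair:
            px, py = placed_xy[-1]
            pr = radii[-1]
            theta = rng.uniform(0, 2 * np.pi)
            d = 0.95 * (pr + r)
            x, y = px + d * np.cos(theta), py + d * np.sin(theta)
            if not polygon.covers(Point(x, y)):
                continue
            # a touching partner only needs clearance from everything but
            # its partner
            others = placed_xy[:-1]
        else:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if not polygon.covers(Point(x, y)):
                continue
            others = placed_xy
        if others:
            arr = np.asarray(others)
            dist = np.hypot(arr[:, 0] - x, arr[:, 1] - y)
            rsum = np.asarray(radii[: len(others)]) + r
            min_allowed = np.maximum(min_sep_factor * rsum, rsum + min_clearance)
            if np.any(dist < min_allowed):
                continue
        placed_xy.append((x, y))
        radii.append(r)
        touching.append(bool(make_pair))
    return (
        np.asarray(placed_xy).reshape(-1, 2),
        np.asarray(radii),
        np.asarray(touching, dtype=bool),
    )


# --------------------------------------------------------------------------
# rasterized primitives


def _stamp_gaussian_disc(canvas, x_um, y_um, radius_um, peak, ps) -> None:
    """Additive Gaussian-profiled disc (nucleus).

    sigma is half the nominal radius so the blob that survives detection
    thresholds on the expected scale has roughly the nominal radius, and
    the expansion ring around it stays on the soma.
    """
    sigma = radius_um / 2.0
    half = 2.2 * radius_um
    h, w = canvas.shape
    c0 = max(int((x_um - half) / ps), 0)
    c1 = min(int((x_um + half) / ps) + 1, w)
    r0 = max(int((y_um - half) / ps), 0)
    r1 = min(int((y_um + half) / ps) + 1, h)
    if c1 <= c0 or r1 <= r0:
        return
    xs = (np.arange(c0, c1) + 0.5) * ps - x_um
    ys = (np.arange(r0, r1) + 0.5) * ps - y_um
    rr2 = ys[:, None] ** 2 + xs[None, :] ** 2
    canvas[r0:r1, c0:c1] += peak * np.exp(-rr2 / (2 * sigma**2))


def _stamp_soft_ellipse(canvas, x_um, y_um, a_um, b_um, angle, value, ps, edge_um=1.0):
    """Flat-top elliptical soma with a soft linear edge; max-composited."""
    half = max(a_um, b_um) + edge_um
    h, w = canvas.shape
    c0 = max(int((x_um - half) / ps), 0)
    c1 = min(int((x_um + half) / ps) + 1, w)
    r0 = max(int((y_um - half) / ps), 0)
    r1 = min(int((y_um + half) / ps) + 1, h)
    if c1 <= c0 or r1 <= r0:
        return
    xs = (np.arange(c0, c1) + 0.5) * ps - x_um
    ys = (np.arange(r0, r1) + 0.5) * ps - y_um
    xx = xs[None, :]
    yy = ys[:, None]
    ca, sa = np.cos(angle), np.sin(angle)
    xr = xx * ca + yy * sa
    yr = -xx * sa + yy * ca
    # distance-like field: 0 at center, 1 on the ellipse boundary
    re = np.sqrt((xr / a_um) ** 2 + (yr / b_um) ** 2)
    # flat top inside, linear fade to zero at the boundary over ~edge_um
    # (edge width approximated via the minor axis)
    soft = np.clip((1.0 - re) * b_um / edge_um, 0.0, 1.0)
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, value * soft, out=patch)


def _draw_polyline(canvas_bool, pts_um, ps) -> None:
    """Mark single-pixel line segments on a boolean canvas."""
    from skimage.draw import line

    h, w = canvas_bool.shape
    px = np.clip((np.asarray(pts_um) / ps).astype(int), 0, [w - 1, h - 1])
    for (x0, y0), (x1, y1) in zip(px[:-1], px[1:]):
        rr, cc = line(y0, x0, y1, x1)
        canvas_bool[rr, cc] = True


def _draw_weighted_polyline(canvas, pts_um, value, ps) -> None:
    """Max-composite single-pixel line segments at a given intensity."""
    from skimage.draw import line

    h, w = canvas.shape
    px = np.clip((np.asarray(pts_um) / ps).astype(int), 0, [w - 1, h - 1])
    for (x0, y0), (x1, y1) in zip(px[:-1], px[1:]):
        rr, cc = line(y0, x0, y1, x1)
        np.maximum.at(canvas, (rr, cc), value)


def _widen(lines_bool, width_um, ps) -> np.ndarray:
    """Grow 1-px center-lines into stripes of the given physical width."""
    if not lines_bool.any():
        return lines_bool.copy()
    d = ndi.distance_transform_edt(~lines_bool)
    return d <= (width_um / 2.0) / ps


# --------------------------------------------------------------------------
# main generator


def generate_section(
    config: SectionConfig,
) -> tuple[SectionImage, list[GroundTruthCell], AnnotationSet]:
    """Render one synthetic section and return it with its ground truth.

    The returned AnnotationSet holds the region polygons (role ``region``)
    and the true tissue outline (role ``tissue``), in pixel coordinates.
    Identical configs (including seed) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ps = config.pixel_size_um
    shape = config.shape_px
    channels = {
        name: np.zeros(shape, dtype=np.float64) for name in ("DAPI", "DsRed", "GFP")
    }

    tissue_um = config.tissue_polygon_um
    tissue_px_poly = _scale(tissue_um, xfact=1 / ps, yfact=1 / ps, origin=(0, 0))
    tissue_mask = rasterize_geometry(tissue_px_poly, shape)
    region_masks = {
        name: rasterize_geometry(
            _scale(geom, xfact=1 / ps, yfact=1 / ps, origin=(0, 0)), shape
        )
        for name, geom in config.regions
    }

    # background levels
    for cname, canvas in channels.items():
        bg = config.background[cname]
        canvas += bg.outside
        canvas[tissue_mask] = bg.tissue
        for rname, rmask in region_masks.items():
            canvas[rmask] = bg.region_level(rname)

    # edge brightening: additive ramp in a band just inside the tissue edge
    if config.edge_brightening_amplitude > 0 and tissue_mask.any():
        d_in = ndi.distance_transform_edt(tissue_mask) * ps
        ramp = config.edge_brightening_amplitude * np.clip(
            1.0 - d_in / config.edge_brightening_width_um, 0.0, 1.0
        )
        ramp[~tissue_mask] = 0.0
        for canvas in channels.values():
            canvas += ramp

    # ---- place cells -----------------------------------------------------
    cells: list[GroundTruthCell] = []
    for name, geom in config.regions:
        density = float(config.nucleus_density.get(name, 0.0))
        if density <= 0:
            continue
        area_mm2 = geom.area / 1e6
        n = int(rng.poisson(density * area_mm2))
        if n == 0:
            continue
        xy, radii, touching = _sample_positions(
            rng,
            geom,
            n,
            config.nucleus_radius_um,
            config.nucleus_radius_sd_um,
            config.min_separation_factor,
            config.min_clearance_um,
            config.touching_fraction,
            name,
        )
        pf = float(config.pericyte_fraction.get(name, 0.0))
        mf = float(config.microglia_fraction.get(name, 0.0))
        # both members of a deliberately touching pair stay negative (the
        # pairs exist to exercise watershed splitting, not to put an
        # expansion ring inside a marker-bright soma); fractions are
        # renormalized over the free cells so the marginal class
        # fractions still match the configuration exactly
        anchored = np.zeros(n, dtype=bool)
        anchored[:-1] = touching[1:]
        paired = touching | anchored
        n_free = int((~paired).sum())
        scale = n / n_free if n_free else 0.0
        u = rng.random(n)
        classes = np.where(
            u < pf * scale,
            PERICYTE,
            np.where(u < (pf + mf) * scale, MICROGLIA, NEGATIVE),
        )
        classes = np.where(paired, NEGATIVE, classes)
        dim = rng.random(n) < config.dim_fraction
        dapi = config.dapi_nucleus.draw(rng, n)
        dapi[dim] *= config.dim_factor
        dsred_v = config.dsred_soma.draw(rng, n)
        gfp_v = config.gfp_soma.draw(rng, n)
        for k in range(n):
            cells.append(
                GroundTruthCell(
                    id=len(cells),
                    x_um=float(xy[k, 0]),
                    y_um=float(xy[k, 1]),
                    radius_um=float(radii[k]),
                    cell_class=str(classes[k]),
                    region=name,
                    dim=bool(dim[k]),
                    dapi_peak=float(dapi[k]),
                    dsred_value=float(dsred_v[k]) if classes[k] == PERICYTE else 0.0,
                    gfp_value=float(gfp_v[k]) if classes[k] == MICROGLIA else 0.0,
                )
            )

    # ---- vasculature (DsRed) --------------------------------------------
    cap_lines = np.zeros(shape, dtype=bool)
    tissue_area_mm2 = tissue_um.area / 1e6
    n_cap = int(rng.poisson(config.capillaries_per_mm2 * tissue_area_mm2))
    minx, miny, maxx, maxy = tissue_um.bounds
    for _ in range(n_cap):
        x0 = rng.uniform(minx, maxx)
        y0 = rng.uniform(miny, maxy)
        theta = rng.uniform(0, 2 * np.pi)
        length = max(40.0, rng.normal(150.0, 50.0))
        x1, y1 = x0 + length * np.cos(theta), y0 + length * np.sin(theta)
        _draw_polyline(cap_lines, [(x0, y0), (x1, y1)], ps)
    # every pericyte sits on a short capillary segment through its soma
    pericytes = [c for c in cells if c.cell_class == PERICYTE]
    peri_angle = {}
    for c in pericytes:
        theta = rng.uniform(0, 2 * np.pi)
        peri_angle[c.id] = theta
        dx, dy = 40.0 * np.cos(theta), 40.0 * np.sin(theta)
        _draw_polyline(
            cap_lines, [(c.x_um - dx, c.y_um - dy), (c.x_um + dx, c.y_um + dy)], ps
        )
    cap_mask = _widen(cap_lines, config.capillary_width_um, ps) & tissue_mask
    channels["DsRed"][cap_mask] += config.capillary_intensity

    vessel_lines = np.zeros(shape, dtype=bool)
    vessel_paths_um: list[tuple[tuple[float, float], tuple[float, float]]] = []
    for _ in range(int(config.large_vessel_count)):
        x0 = rng.uniform(minx, maxx)
        y0 = rng.uniform(miny, maxy)
        theta = rng.uniform(0, 2 * np.pi)
        ext = 0.45 * max(config.width_um, config.height_um)
        p0 = (x0 - ext * np.cos(theta), y0 - ext * np.sin(theta))
        p1 = (x0 + ext * np.cos(theta), y0 + ext * np.sin(theta))
        vessel_paths_um.append((p0, p1))
        _draw_polyline(vessel_lines, [p0, p1], ps)
    vessel_mask = _widen(vessel_lines, config.large_vessel_width_um, ps) & tissue_mask
    channels["DsRed"][vessel_mask] += config.large_vessel_intensity

    # ---- somata and processes -------------------------------------------
    gfp_process = np.zeros(shape, dtype=np.float64)
    for c in cells:
        r = c.radius_um
        if c.cell_class == PERICYTE:
            # elongated along its capillary; flat top still covers the
            # 2 um expansion ring so the class is learnable from cell means
            _stamp_soft_ellipse(
                channels["DsRed"],
                c.x_um,
                c.y_um,
                r + 3.8,
                r + 2.9,
                peri_angle[c.id],
                c.dsred_value,
                ps,
                edge_um=0.8,
            )
        elif c.cell_class == MICROGLIA:
            _stamp_soft_ellipse(
                channels["GFP"], c.x_um, c.y_um, r + 3.5, r + 3.5, 0.0, c.gfp_value, ps
            )
            for _ in range(int(rng.integers(2, 6))):
                theta = rng.uniform(0, 2 * np.pi)
                pts = [(c.x_um + (r + 3.0) * np.cos(theta), c.y_um + (r + 3.0) * np.sin(theta))]
                for _ in range(int(rng.integers(6, 13))):
                    theta += rng.normal(0, 0.6)
                    pts.append(
                        (pts[-1][0] + 2.5 * np.cos(theta), pts[-1][1] + 2.5 * np.sin(theta))
                    )
                # processes are dim relative to somata so that a process
                # crossing a neighboring cell's expansion ring cannot lift
                # that cell's mean into the classification grid
                _draw_weighted_polyline(gfp_process, pts, 0.30 * c.gfp_value, ps)
    channels["GFP"] += gfp_process

    # nuclei last (DAPI is independent of the other channels)
    for c in cells:
        _stamp_gaussian_disc(channels["DAPI"], c.x_um, c.y_um, c.radius_um, c.dapi_peak, ps)

    # ---- noise and quantization -----------------------------------------
    stack = np.stack([channels[n] for n in ("DAPI", "DsRed", "GFP")])
    stack += rng.normal(0.0, config.noise_sd, size=stack.shape)
    stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    img = SectionImage(stack, ("DAPI", "DsRed", "GFP"), ps)

    annots = [
        Annotation(
            name,
            _scale(geom, xfact=1 / ps, yfact=1 / ps, origin=(0, 0)),
            role="region",
        )
        for name, geom in config.regions
    ]
    annots.append(Annotation("tissue", tissue_px_poly, role="tissue"))
    if vessel_paths_um:
        from shapely.geometry import LineString
        from shapely.ops import unary_union

        vessel_geom = unary_union(
            [
                LineString([(p0[0] / ps, p0[1] / ps), (p1[0] / ps, p1[1] / ps)])
                for p0, p1 in vessel_paths_um
            ]
        ).buffer((config.large_vessel_width_um / 2.0) / ps)
        annots.append(Annotation("large-vessels", vessel_geom, role="vessels"))
    return img, cells, AnnotationSet(annots)


# --------------------------------------------------------------------------
# test annotations and ground-truth counting


def generate_test_annotations(
    regions: AnnotationSet,
    size_um: tuple[float, float] = (300.0, 200.0),
    seed: int = 0,
    pixel_size_um: float = 1.0,
    avoid=None,
) -> AnnotationSet:
    """Place one axis-aligned test rectangle fully inside each region.

    ``avoid`` optionally gives a geometry (pixel coordinates, e.g. a
    buffered large-vessel mask outline) the rectangle must not intersect,
    mirroring how ROIs for manual counting are drawn in clean tissue.
    """
    rng = np.random.default_rng(seed)
    w_px = size_um[0] / pixel_size_um
    h_px = size_um[1] / pixel_size_um
    out = []
    for region in regions.by_role("region"):
        minx, miny, maxx, maxy = region.geometry.bounds
        if maxx - minx < w_px - 1e-9 or maxy - miny < h_px - 1e-9:
            raise ValueError(
                f"region {region.name!r} is too small for a "
                f"{size_um[0]} x {size_um[1]} um test annotation"
            )
        rect = None
        for attempt in range(4000):
            x0 = rng.uniform(minx, maxx - w_px) if maxx - minx > w_px else minx
            y0 = rng.uniform(miny, maxy - h_px) if maxy - miny > h_px else miny
            cand = box(x0, y0, x0 + w_px, y0 + h_px)
            if not region.geometry.covers(cand):
                continue
            # prefer clean tissue, but fall back to any contained placement
            # when the avoid constraint leaves no room
            if avoid is not None and attempt < 2000 and cand.intersects(avoid):
                continue
            if avoid is not None and attempt >= 2000 and cand.intersects(avoid):
                import warnings

                warnings.warn(
                    f"test annotation in region {region.name!r} overlaps "
                    "avoided geometry; no clean placement found",
                    stacklevel=2,
                )
            rect = cand
            break
        if rect is None:
            raise ValueError(
                f"could not place a {size_um[0]} x {size_um[1]} um test "
                f"annotation inside region {region.name!r}"
            )
        out.append(Annotation(region.name, rect, role="test-rect"))
    return AnnotationSet(out)


def ground_truth_counts(
    cells: Sequence[GroundTruthCell], polygon: Polygon | MultiPolygon
) -> CountTriple:
    """Count ground-truth cells whose centroid falls inside a polygon (um).

    Boundary convention: a centroid exactly on the polygon boundary counts
    as inside (shapely ``covers``).
    """
    if not cells:
        return CountTriple(0, 0, 0)
    pts = shapely.points([(c.x_um, c.y_um) for c in cells])
    inside = shapely.covers(polygon, pts)
    total = int(inside.sum())
    dsred = int(sum(1 for c, i in zip(cells, inside) if i and c.cell_class == PERICYTE))
    gfp = int(sum(1 for c, i in zip(cells, inside) if i and c.cell_class == MICROGLIA))
    return CountTriple(total, dsred, gfp)


GROUND_TRUTH_COLUMNS = ["id", "x_um", "y_um", "radius_um", "class", "region"]


def write_ground_truth(cells: Sequence[GroundTruthCell], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": c.id,
                "x_um": c.x_um,
                "y_um": c.y_um,
                "radius_um": c.radius_um,
                "class": c.cell_class,
                "region": c.region,
            }
            for c in cells
        ],
        columns=GROUND_TRUTH_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_ground_truth(path) -> list[GroundTruthCell]:
    df = pd.read_csv(path)
    return [
        GroundTruthCell(
            id=int(r.id),
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            radius_um=float(r.radius_um),
            cell_class=str(r["class"]),
            region=str(r.region),
        )
        for _, r in df.iterrows()
    ]
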