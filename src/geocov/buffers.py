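"""Circular-buffer summaries.

Three families: road-length sums (segments clipped at the buffer
boundary, three weightings), areal-weighted polygon-attribute sums
(uniform within-polygon density), and land-use area proportions. Buffer
discs are 256-vertex polygon approximations (area error < 0.01%).

Units follow the output conventions of the covariate table: road sums in
km (plain length and length x lanes) or 10^3 m^2 (length x lanes x
width); census sums in counts; land-use values as fractions of the
buffer area; emission sums in the inventory's mass/year unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from geocov.errors import ConfigurationError, GeocovError, SchemaError
from geocov.model import (
    DEFAULT_SCHEME,
    EmissionGridTable,
    Feature,
    MonitoringSite,
    POLLUTANTS,
    RoadClassScheme,
    RoadSegment,
    WidthTable,
    ZonalPolygonLayer,
    square_cell,
)
from geocov.proximity import classify_road, classify_urban

#: Default buffer radii (meters) by category.
TRAFFIC_RADII = (25.0, 50.0, 100.0, 300.0, 500.0, 1000.0)
NONTRAFFIC_RADII = (50.0, 100.0, 300.0, 500.0, 1000.0, 5000.0)
NONTRAFFIC_RADII_NO50 = (100.0, 300.0, 500.0, 1000.0, 5000.0)
EMISSION_RADII = (3000.0, 15000.0, 30000.0)

RADII_PRESETS = {
    "traffic": TRAFFIC_RADII,
    "nontraffic_table1": NONTRAFFIC_RADII,
    "nontraffic_text": NONTRAFFIC_RADII_NO50,
    "emission": EMISSION_RADII,
}

WEIGHTINGS = ("length", "length_x_lanes", "length_x_lanes_x_width")

#: m -> km for lengths, m^2 -> 10^3 m^2 for length x lanes x width.
_UNIT_SCALE = 1e-3

BUFFER_QUAD_SEGS = 64  # 4 * 64 = 256 vertices per disc


@dataclass(frozen=True)
class BufferSpec:
    category: str  # traffic | nontraffic | emission
    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.radii:
            raise ConfigurationError("BufferSpec needs at least one radius")
        if any(r <= 0 for r in self.radii):
            raise ConfigurationError("buffer radii must be > 0")
        if list(self.radii) != sorted(set(self.radii)):
            raise ConfigurationError("buffer radii must be strictly increasing")


@dataclass(frozen=True)
class BufferSummary:
    site_id: str
    radius: float
    variable: str
    value: float


def buffer_disc(site: MonitoringSite, radius: float, quad_segs: int = BUFFER_QUAD_SEGS) -> Polygon:
    if radius <= 0:
        raise GeocovError("buffer radius must be > 0")
    return Point(site.x, site.y).buffer(radius, quad_segs=quad_segs)


def road_sum_in_buffer(
    site: MonitoringSite,
    radius: float,
    roads: Sequence[RoadSegment],
    road_class: str = "ALL",
    weighting: str = "length",
    width_table: WidthTable | None = None,
    urbanized: ZonalPolygonLayer | None = None,
    scheme: RoadClassScheme = DEFAULT_SCHEME,
    quad_segs: int = BUFFER_QUAD_SEGS,
) -> float:
    """Raw clipped road sum in meters-based units (m, lane-m, or m^2).

    Segments of the requested class are clipped to the buffer disc before
    summing, so the value is continuous in the radius. Empty intersection
    is a valid 0, not missing.
    """
    if weighting not in WEIGHTINGS:
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if weighting == "length_x_lanes_x_width":
        if width_table is None:
            raise ConfigurationError("length_x_lanes_x_width needs a width table")
        if urbanized is None:
            raise ConfigurationError(
                "length_x_lanes_x_width needs an urbanized-area layer for the "
                "urban/non-urban width rule"
            )
    disc = buffer_disc(site, radius, quad_segs=quad_segs)
    prepared = prep(disc)
    total = 0.0
    for seg in roads:
        if road_class != "ALL" and road_class not in classify_road(seg, scheme):
            continue
        if not prepared.intersects(seg.geometry):
            continue
        clipped = seg.geometry.intersection(disc)
        length = clipped.length
        if length == 0.0:
            continue
        if weighting == "length":
            total += length
        elif weighting == "length_x_lanes":
            total += length * seg.lanes
        else:
            is_urban = classify_urban(seg, urbanized)
            width = width_table.lookup(seg.is_highway, seg.speed_limit, is_urban)
            total += length * seg.lanes * width
    return total


def buffer_road_sum(
    site: MonitoringSite,
    radius: float,
    roads: Sequence[RoadSegment],
    road_class: str = "ALL",
    weighting: str = "length",
    width_table: WidthTable | None = None,
    urbanized: ZonalPolygonLayer | None = None,
    scheme: RoadClassScheme = DEFAULT_SCHEME,
) -> BufferSummary:
    """Clipped road sum as a table cell: km, lane-km, or 10^3 m^2."""
    raw = road_sum_in_buffer(
        site, radius, roads, road_class, weighting, width_table, urbanized, scheme
    )
    name = f"traffic.road_sum.{road_class}.{weighting}.{int(radius)}m"
    return BufferSummary(site.site_id, radius, name, raw * _UNIT_SCALE)


def areal_weighted_sum_over(
    region: Polygon, zones: ZonalPolygonLayer, attribute: str
) -> float:
    """Areal-weighted attribute total over an arbitrary polygon region.

    Each intersecting polygon j contributes attr_j * area(j ∩ region) /
    area(j) — i.e. counts are assumed uniformly spread within their
    polygon. Zero-area intersections (mere boundary touches) contribute
    nothing, as do missing (None) attribute values.
    """
    prepared = prep(region)
    total = 0.0
    for f in zones:
        if attribute not in f.attributes:
            raise SchemaError(
                f"polygon {f.feature_id!r} has no attribute {attribute!r}"
            )
        value = f.attributes[attribute]
        if value is None:
            continue
        if not prepared.intersects(f.geometry):
            continue
        inter = f.geometry.intersection(region).area
        if inter > 0.0:
            total += float(value) * inter / f.geometry.area
    return total


def areal_weighted_sum(
    site: MonitoringSite,
    radius: float,
    zones: ZonalPolygonLayer,
    attribute: str,
    quad_segs: int = BUFFER_QUAD_SEGS,
) -> BufferSummary:
    """Buffer total of a polygon count attribute under areal weighting."""
    disc = buffer_disc(site, radius, quad_segs=quad_segs)
    total = areal_weighted_sum_over(disc, zones, attribute)
    name = f"demographic.{attribute}.{int(radius)}m"
    return BufferSummary(site.site_id, radius, name, total)


def land_use_proportion(
    site: MonitoringSite,
    radius: float,
    landcover: ZonalPolygonLayer,
    class_code: str,
    class_attribute: str = "class_code",
    quad_segs: int = BUFFER_QUAD_SEGS,
) -> BufferSummary:
    """Fraction of the buffer covered by one land-use class, in [0, 1].

    The denominator is the area of the discretized buffer polygon itself,
    so proportions over a mosaic that tessellates the buffer sum exactly
    to 1. Classes absent from the buffer yield 0.
    """
    disc = buffer_disc(site, radius, quad_segs=quad_segs)
    prepared = prep(disc)
    covered = 0.0
    for f in landcover:
        if f.attributes.get(class_attribute) != class_code:
            continue
        if not prepared.intersects(f.geometry):
            continue
        covered += f.geometry.intersection(disc).area
    name = f"landuse.{class_code}.{int(radius)}m"
    fraction = min(max(covered / disc.area, 0.0), 1.0)  # clamp fp roundoff
    return BufferSummary(site.site_id, radius, name, fraction)


def emission_cells_to_polygons(table: EmissionGridTable) -> ZonalPolygonLayer:
    """Square grid-cell polygons with per-pollutant totals.

    Each distinct bottom-left corner becomes the half-open square
    [x, x+size) x [y, y+size); point + line + area source estimates are
    summed per (cell, pollutant). Adjacent cells tile without overlap.
    """
    sums: dict[tuple[float, float], dict[str, float]] = {}
    for c in table.cells:
        key = (c.corner_x, c.corner_y)
        attrs = sums.setdefault(key, {})
        attrs[c.pollutant] = attrs.get(c.pollutant, 0.0) + c.estimate
    features = []
    for i, ((cx, cy), attrs) in enumerate(sorted(sums.items())):
        full = {p: attrs.get(p, 0.0) for p in POLLUTANTS}
        features.append(
            Feature(
                feature_id=f"cell_{i}",
                geometry=square_cell(cx, cy, table.cell_size),
                attributes=full,
            )
        )
    return ZonalPolygonLayer(features, layer_kind="emission_cell")


def emission_buffer_sum(
    site: MonitoringSite,
    radius: float,
    emission_polygons: ZonalPolygonLayer,
    pollutant: str,
) -> BufferSummary:
    """Areal-weighted emission total within a large buffer."""
    if pollutant not in POLLUTANTS:
        raise ConfigurationError(f"unknown pollutant {pollutant!r}")
    inner = areal_weighted_sum(site, radius, emission_polygons, pollutant)
    name = f"emission.{pollutant}.{int(radius)}m"
    return BufferSummary(site.site_id, radius, name, inner.value)
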