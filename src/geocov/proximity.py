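"""Nearest-feature distances and road classification.

Distances are minimum planar Euclidean point-to-geometry distances:
distance to a polyline includes segment interiors, distance to a polygon
is 0 when the point is inside. An entirely empty target layer yields a
*missing* result (never a fabricated large number).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from shapely.geometry.base import BaseGeometry
from shapely.geometry import LineString, MultiLineString
from shapely.ops import unary_union

from geocov.errors import GeocovError
from geocov.model import (
    DEFAULT_SCHEME,
    Feature,
    MonitoringSite,
    PointFeatureLayer,
    RoadClassScheme,
    RoadSegment,
    ZonalPolygonLayer,
)

logger = logging.getLogger(__name__)

ROAD_CLASSES = ("ALL", "MR1", "MR2")


@dataclass(frozen=True)
class DistanceResult:
    site_id: str
    target: str
    distance: float | None  # meters; None == missing (empty target layer)
    nearest_feature_id: str | None

    @property
    def is_missing(self) -> bool:
        return self.distance is None


def _iter_id_geoms(features):
    """Normalize the accepted feature containers to (id, geometry) pairs."""
    for i, f in enumerate(features):
        if isinstance(f, Feature):
            yield f.feature_id, f.geometry
        elif isinstance(f, RoadSegment):
            yield f.segment_id, f.geometry
        elif isinstance(f, BaseGeometry):
            yield str(i), f
        else:
            fid, geom = f
            yield str(fid), geom


def nearest_distance(site: MonitoringSite, features, target: str = "") -> DistanceResult:
    """Minimum Euclidean distance from a site to any feature in a layer.

    ``features`` may be a layer object, a list of Feature/RoadSegment, raw
    shapely geometries, or (id, geometry) pairs. Equidistant features are
    broken deterministically toward the lowest feature id (string order).
    """
    if isinstance(features, (ZonalPolygonLayer, PointFeatureLayer)):
        features = features.features
    pairs = sorted(_iter_id_geoms(features), key=lambda p: p[0])
    if not pairs:
        logger.warning("nearest_distance: empty feature list for target %r "
                       "at site %s; emitting missing", target, site.site_id)
        return DistanceResult(site.site_id, target, None, None)
    pt = site.point
    best_id, best_d = None, math.inf
    for fid, geom in pairs:
        d = pt.distance(geom)
        if d < best_d:
            best_id, best_d = fid, d
    return DistanceResult(site.site_id, target, best_d, best_id)


def road_class_share(class_length: float, total_length: float, ndigits: int = 2) -> float:
    """Percentage of total road length belonging to a class, rounded.

    E.g. national class totals in km give the share printed for major-road
    classes; units cancel so any consistent length unit works.
    """
    if total_length <= 0:
        raise GeocovError("total_length must be > 0")
    if class_length < 0:
        raise GeocovError("class_length must be >= 0")
    return round(100.0 * class_length / total_length, ndigits)


def classify_road(segment: RoadSegment, scheme: RoadClassScheme = DEFAULT_SCHEME) -> set[str]:
    """Road classes a segment belongs to: always ALL; MR1 by road type;
    MR2 = MR1 plus local roads with strictly more than the lane threshold."""
    classes = {"ALL"}
    if segment.road_type in scheme.mr1_types:
        classes |= {"MR1", "MR2"}
    elif segment.lanes > scheme.mr2_lane_threshold:
        classes.add("MR2")
    return classes


def classify_urban(segment: RoadSegment, urbanized: ZonalPolygonLayer) -> bool:
    """True iff the segment intersects any urbanized-area polygon
    (touching the boundary counts)."""
    return any(segment.geometry.intersects(f.geometry) for f in urbanized)


def assign_width(segment: RoadSegment, is_urban: bool, table) -> float:
    """Width (m) for the segment's (highway flag, speed band, urban flag)."""
    return table.lookup(segment.is_highway, segment.speed_limit, is_urban)


def filter_major_ports(ports: PointFeatureLayer, threshold: float = 10000.0) -> PointFeatureLayer:
    """Keep ports with strictly more than ``threshold`` vessels per year."""
    kept = [f for f in ports if f.attributes["vessels_per_year"] > threshold]
    return PointFeatureLayer(kept, kind=ports.kind)


def derive_border_line(
    admin: ZonalPolygonLayer, northern_fraction: float = 0.1
) -> LineString | MultiLineString:
    """Northern portion of the dissolved outer boundary of an admin layer.

    Dissolves all polygons, takes the exterior ring of the largest part,
    and keeps the ring segments whose midpoints lie in the top
    ``northern_fraction`` of the ring's y-extent. Multi-part regions use
    the largest part (by area) with a warning.
    """
    if len(admin) == 0:
        raise GeocovError("derive_border_line: empty admin layer")
    if not 0 < northern_fraction <= 1:
        raise GeocovError("northern_fraction must be in (0, 1]")
    dissolved = unary_union(admin.geometries())
    if dissolved.geom_type == "MultiPolygon":
        parts = sorted(dissolved.geoms, key=lambda g: g.area, reverse=True)
        logger.warning(
            "derive_border_line: %d disjoint parts; using the largest "
            "(area %.1f of %.1f)", len(parts), parts[0].area, dissolved.area,
        )
        dissolved = parts[0]
    ring = dissolved.exterior
    ys = [c[1] for c in ring.coords]
    y_min, y_max = min(ys), max(ys)
    cutoff = y_max - northern_fraction * (y_max - y_min)

    coords = list(ring.coords)
    segs = []
    for a, b in zip(coords[:-1], coords[1:]):
        if (a[1] + b[1]) / 2.0 > cutoff:  # strict: segments at the cutoff stay out
            segs.append(LineString([a, b]))
    if not segs:
        raise GeocovError("derive_border_line: no boundary segments in the northern band")
    merged = unary_union(segs)
    if merged.geom_type == "GeometryCollection":
        merged = MultiLineString(
            [g for g in merged.geoms if g.geom_type == "LineString"]
        )
    return merged
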