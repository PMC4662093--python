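"""Domain types and validated in-memory representations.

All coordinates are projected easting/northing in meters; computation is
planar Euclidean. Mixing coordinate systems is rejected at the loading
boundary (see :mod:`geocov.io`), never checked again downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.geometry import LineString, Point, Polygon

from geocov.errors import ConfigurationError, LayerValidationError, SchemaError


class SiteType(str, Enum):
    urban_background = "urban_background"
    urban_roadside = "urban_roadside"
    other = "other"


#: The eight road classes of the national road-network database.
ROAD_TYPES = (
    "national_highway",
    "metro_city_highway",
    "general_national_road",
    "metro_city_road",
    "gov_provincial_road",
    "provincial_road",
    "district_road",
    "highway_link_ramp",
)

#: Pollutants carried by the national 1-km emission inventory.
POLLUTANTS = ("CO", "NOx", "SOx", "TSP", "PM10", "VOC", "NH3")

EMISSION_SOURCES = ("point", "line", "area")

#: The 12 land-cover classes used for land-use proportions: the six
#: medium-level urban classes plus six non-urban high-level classes.
LAND_USE_CLASSES = (
    "residential",
    "industrial",
    "commercial",
    "cultural",
    "transportation",
    "public_facility",
    "agricultural",
    "forest",
    "grassland",
    "wetland",
    "bare_ground",
    "water",
)


@dataclass(frozen=True)
class MonitoringSite:
    """A point location at which covariates are evaluated."""

    site_id: str
    x: float
    y: float
    site_type: SiteType = SiteType.other

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise LayerValidationError(
                f"site {self.site_id!r}: non-finite coordinates ({self.x}, {self.y})"
            )
        if isinstance(self.site_type, str) and not isinstance(self.site_type, SiteType):
            object.__setattr__(self, "site_type", SiteType(self.site_type))

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


def validate_sites(sites: Sequence[MonitoringSite]) -> None:
    """Enforce site_id uniqueness within a site set."""
    seen: set[str] = set()
    for s in sites:
        if s.site_id in seen:
            raise LayerValidationError(f"duplicate site_id {s.site_id!r}")
        seen.add(s.site_id)


@dataclass
class RoadSegment:
    """A road centerline with the attributes needed for classification
    and width assignment."""

    segment_id: str
    geometry: LineString
    road_type: str
    lanes: int
    speed_limit: float
    is_highway: bool = False

    def __post_init__(self) -> None:
        if self.road_type not in ROAD_TYPES:
            raise SchemaError(
                f"segment {self.segment_id!r}: unknown road_type {self.road_type!r}"
            )
        if len(self.geometry.coords) < 2:
            raise LayerValidationError(
                f"segment {self.segment_id!r}: geometry needs >= 2 vertices"
            )
        if int(self.lanes) < 1:
            raise LayerValidationError(
                f"segment {self.segment_id!r}: lanes must be >= 1, got {self.lanes}"
            )
        self.lanes = int(self.lanes)
        if not self.speed_limit > 0:
            raise LayerValidationError(
                f"segment {self.segment_id!r}: speed_limit must be > 0"
            )


@dataclass(frozen=True)
class RoadClassScheme:
    """Which road types form MR1 and how many lanes promote a local road
    into MR2 (strictly more than ``mr2_lane_threshold`` lanes)."""

    mr1_types: frozenset[str] = frozenset({"national_highway", "metro_city_highway"})
    mr2_lane_threshold: int = 6

    def __post_init__(self) -> None:
        if not self.mr1_types:
            raise ConfigurationError("mr1_types must be non-empty")
        if self.mr2_lane_threshold < 1:
            raise ConfigurationError("mr2_lane_threshold must be >= 1")
        unknown = set(self.mr1_types) - set(ROAD_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown road types in mr1_types: {sorted(unknown)}")


DEFAULT_SCHEME = RoadClassScheme()


@dataclass(frozen=True)
class WidthRow:
    is_highway: bool
    speed_min: float  # inclusive
    speed_max: float  # exclusive
    is_urban: bool
    width_m: float


class WidthTable:
    """Road-width lookup by (highway flag, speed band, urban flag).

    Speed bands are half-open ``[speed_min, speed_max)``. The shipped
    default (:meth:`default`) uses plausible per-lane widths and is NOT
    an authoritative reproduction of any administrative rule; supply a
    CSV (is_highway,speed_min,speed_max,is_urban,width_m) for real work.
    """

    def __init__(self, rows: Iterable[WidthRow]):
        self.rows = list(rows)
        if not self.rows:
            raise ConfigurationError("width table has no rows")
        for r in self.rows:
            if not r.width_m > 0:
                raise ConfigurationError(f"non-positive width in row {r}")
            if not r.speed_min < r.speed_max:
                raise ConfigurationError(f"empty speed band in row {r}")

    def lookup(self, is_highway: bool, speed_limit: float, is_urban: bool) -> float:
        for r in self.rows:
            if (
                r.is_highway == bool(is_highway)
                and r.is_urban == bool(is_urban)
                and r.speed_min <= speed_limit < r.speed_max
            ):
                return r.width_m
        raise ConfigurationError(
            "width table does not cover combination "
            f"(is_highway={is_highway}, speed_limit={speed_limit}, is_urban={is_urban})"
        )

    @classmethod
    def default(cls) -> "WidthTable":
        rows = []
        for is_urban in (False, True):
            rows += [
                WidthRow(True, 0.0, 80.0, is_urban, 3.25 if is_urban else 3.5),
                WidthRow(True, 80.0, 121.0, is_urban, 3.5 if is_urban else 3.6),
                WidthRow(False, 0.0, 60.0, is_urban, 3.0),
                WidthRow(False, 60.0, 80.0, is_urban, 3.25),
                WidthRow(False, 80.0, 121.0, is_urban, 3.5),
            ]
        return cls(rows)


@dataclass
class Feature:
    """A geometry plus a flat attribute map. ``None`` marks a missing
    attribute value (distinct from 0)."""

    feature_id: str
    geometry: BaseGeometry
    attributes: dict = field(default_factory=dict)


class LayerKind(str, Enum):
    census = "census"
    landcover = "landcover"
    admin_district = "admin_district"
    emission_cell = "emission_cell"
    urbanized_area = "urbanized_area"


class PointKind(str, Enum):
    rail_station = "rail_station"
    subway_station = "subway_station"
    bus_stop = "bus_stop"
    airport = "airport"
    port = "port"


class ZonalPolygonLayer:
    """Polygons carrying named numeric attributes (census output areas,
    land cover, administrative districts, emission cells, urbanized areas).

    Zero-area features are rejected at construction; census attribute
    values must be non-negative.
    """

    def __init__(self, features: Iterable[Feature], layer_kind: LayerKind | str):
        self.layer_kind = LayerKind(layer_kind)
        self.features = list(features)
        bad = [f.feature_id for f in self.features if f.geometry.area <= 0]
        if bad:
            raise LayerValidationError(
                f"{self.layer_kind.value} layer: zero-area polygon feature(s) {bad}"
            )
        if self.layer_kind is LayerKind.census:
            for f in self.features:
                for name, v in f.attributes.items():
                    if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                        raise LayerValidationError(
                            f"census feature {f.feature_id!r}: negative {name!r}={v}"
                        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [f.geometry for f in self.features]


class PointFeatureLayer:
    """Point features (stations, stops, airports, ports)."""

    def __init__(self, features: Iterable[Feature], kind: PointKind | str):
        self.kind = PointKind(kind)
        self.features = list(features)
        if self.kind is PointKind.port:
            for f in self.features:
                v = f.attributes.get("vessels_per_year")
                if v is None:
                    raise SchemaError(
                        f"port feature {f.feature_id!r}: missing vessels_per_year"
                    )
                if v < 0:
                    raise LayerValidationError(
                        f"port feature {f.feature_id!r}: vessels_per_year < 0"
                    )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)


@dataclass
class RasterGrid:
    """A regular grid of values on a projected plane.

    ``origin_x, origin_y`` is the outer corner of cell (0, 0); rows run
    bottom-up, so cell (i, j) has the half-open footprint
    ``[origin_x + j*c, origin_x + (j+1)*c) x [origin_y + i*c, origin_y + (i+1)*c)``.
    A point on a shared cell edge therefore belongs to the +x/+y cell.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise LayerValidationError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise LayerValidationError("raster values must be a 2-D matrix")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_index(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/column of the cell containing (x, y), or None if outside."""
        j = math.floor((x - self.origin_x) / self.cell_size)
        i = math.floor((y - self.origin_y) / self.cell_size)
        if 0 <= i < self.n_rows and 0 <= j < self.n_cols:
            return i, j
        return None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-free center coordinates: (xs of cols, ys of rows)."""
        c = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * c
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * c
        return xs, ys

    def is_nodata(self, value: float) -> bool:
        return value == self.nodata or (isinstance(value, float) and math.isnan(value))


class NdviStack:
    """An ordered stack of same-geometry vegetation-index composites
    (typically 36 ten-day composites per year, byte-scaled 0-255)."""

    value_range = (0.0, 255.0)

    def __init__(self, composites: Iterable[tuple["object", RasterGrid]]):
        self.composites = list(composites)
        if not self.composites:
            raise LayerValidationError("empty composite stack")
        ref = self.composites[0][1]
        lo, hi = self.value_range
        for date, grid in self.composites:
            if (
                grid.origin_x != ref.origin_x
                or grid.origin_y != ref.origin_y
                or grid.cell_size != ref.cell_size
                or grid.values.shape != ref.values.shape
            ):
                raise LayerValidationError(
                    f"composite {date}: grid geometry differs from first composite"
                )
            v = grid.values
            valid = ~(np.isnan(v) | (v == grid.nodata))
            if np.any((v[valid] < lo) | (v[valid] > hi)):
                raise LayerValidationError(
                    f"composite {date}: values outside [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.composites)

    def __iter__(self):
        return iter(self.composites)


@dataclass(frozen=True)
class EmissionCell:
    corner_x: float
    corner_y: float
    source: str
    pollutant: str
    estimate: float


class EmissionGridTable:
    """Tabular per-cell annual emission estimates keyed by the bottom-left
    corner of each grid cell."""

    def __init__(self, cells: Iterable[EmissionCell], cell_size: float = 1000.0):
        if not cell_size > 0:
            raise LayerValidationError("cell_size must be > 0")
        self.cell_size = float(cell_size)
        self.cells = list(cells)
        seen: set[tuple] = set()
        for c in self.cells:
            if c.source not in EMISSION_SOURCES:
                raise SchemaError(f"unknown emission source {c.source!r}")
            if c.pollutant not in POLLUTANTS:
                raise SchemaError(f"unknown pollutant {c.pollutant!r}")
            if c.estimate < 0:
                raise LayerValidationError(
                    f"negative emission estimate at ({c.corner_x}, {c.corner_y})"
                )
            key = (c.corner_x, c.corner_y, c.source, c.pollutant)
            if key in seen:
                raise LayerValidationError(f"duplicate emission row {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.cells)


def square_cell(corner_x: float, corner_y: float, size: float) -> Polygon:
    """Axis-aligned grid-cell square with the given bottom-left corner."""
    return Polygon(
        [
            (corner_x, corner_y),
            (corner_x + size, corner_y),
            (corner_x + size, corner_y + size),
            (corner_x, corner_y + size),
        ]
    )
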