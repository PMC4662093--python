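"""Seeded synthetic scenes with closed-form ground truth.

Generates every layer type the pipeline consumes — grid roads, a
rectangular census tessellation with uniform densities, a half-plane
land-cover mosaic, districts, depots, rivers/coastline, a 1-km emission
grid, composite vegetation stacks, and a DEM — from simple analytic
geometries, so that the expected value of each covariate is a closed
form (no oracle needed): road length through a grid node is 4r, a
uniform density integrates to rho*pi*r^2, a half-plane split gives 0.5,
a flat DEM gives 0. Generation is a pure function of the spec (seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon, box

from geocov.errors import GeocovError
from geocov.model import (
    EmissionCell,
    EmissionGridTable,
    Feature,
    MonitoringSite,
    NdviStack,
    PointFeatureLayer,
    POLLUTANTS,
    RasterGrid,
    ROAD_TYPES,
    RoadSegment,
    WidthTable,
    ZonalPolygonLayer,
)
from geocov.buffers import emission_cells_to_polygons
from geocov.pipeline import LayerBundle
from geocov.proximity import derive_border_line

#: Per-attribute density multipliers relative to population density, so
#: every default census attribute is a uniform field with known density.
CENSUS_ATTRIBUTE_WEIGHTS = {
    "population_total": 1.0,
    "households_total": 0.4,
    "housing_detached": 0.1,
    "housing_apartment": 0.2,
    "housing_rowhouse": 0.05,
    "housing_other": 0.05,
    "housing_built_pre1990": 0.1,
    "housing_built_1990s": 0.15,
    "housing_built_2000s": 0.15,
    "companies_agriculture": 0.01,
    "companies_manufacturing": 0.02,
    "companies_construction": 0.02,
    "companies_wholesale_retail": 0.05,
    "companies_lodging_restaurant": 0.04,
    "companies_transport": 0.02,
    "companies_services": 0.06,
    "employees_agriculture": 0.02,
    "employees_manufacturing": 0.15,
    "employees_construction": 0.08,
    "employees_wholesale_retail": 0.2,
    "employees_lodging_restaurant": 0.12,
    "employees_transport": 0.07,
    "employees_services": 0.25,
}


@dataclass(frozen=True)
class SceneSpec:
    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 10000.0, 10000.0)
    n_sites: int = 4
    road_grid_spacing: float = 2000.0
    lane_choices: tuple[int, ...] = (2, 4, 8)
    census_cell_size: float = 1000.0
    population_density: float = 0.01  # persons / m^2
    landcover_split: tuple[str, str] = ("residential", "forest")
    dem_profile: str = "flat"  # flat | ramp | half_plane | random_field
    dem_base: float = 50.0
    dem_cell_size: float = 30.0
    dem_ramp_slope: float = 0.02  # m elevation per m easting (ramp profile)
    dem_step: float = 100.0  # elevation jump of the half_plane profile
    ndvi_profile: str = "constant"  # constant | seasonal
    ndvi_constant: float = 150.0
    ndvi_amplitude: float = 50.0
    ndvi_cell_size: float = 500.0
    emission_per_cell: float = 9.0  # summed over point/line/area sources
    emission_cell_size: float = 1000.0
    n_ports: int = 31
    n_major_ports: int = 10
    port_vessel_threshold: float = 10000.0
    n_depots: int = 8  # per non-port depot kind
    vehicles_monthly_count: float = 5000.0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise GeocovError("extent must have positive area")
        if self.census_cell_size > min(xmax - xmin, ymax - ymin):
            raise GeocovError("census cell larger than extent")
        if self.population_density < 0:
            raise GeocovError("density must be >= 0")
        if self.n_major_ports > self.n_ports:
            raise GeocovError("n_major_ports cannot exceed n_ports")
        if self.dem_profile not in ("flat", "ramp", "half_plane", "random_field"):
            raise GeocovError(f"unknown dem_profile {self.dem_profile!r}")
        if self.ndvi_profile not in ("constant", "seasonal"):
            raise GeocovError(f"unknown ndvi_profile {self.ndvi_profile!r}")


@dataclass
class GroundTruth:
    """Closed-form expected covariate values for a generated scene."""

    node_site_id: str
    roads_through_node: int
    road_grid_spacing: float
    census_densities: dict[str, float]
    landcover_split: tuple[str, str]
    emission_per_cell: float
    emission_cell_size: float
    ndvi_constant: float | None  # None for the seasonal profile
    ndvi_values: tuple[float, ...]  # per-composite values of the current year
    dem_profile: str
    vehicles: float
    river_y: float
    coast_y: float

    def road_length_at_node(self, radius: float) -> float:
        """All-roads clipped length (m) in a node-centered buffer with
        radius << grid spacing: each road through the node is a 2r chord."""
        return 2.0 * radius * self.roads_through_node

    def areal_count(self, attribute: str, radius: float) -> float:
        """Uniform density integrated over the disc: rho * pi * r^2."""
        return self.census_densities[attribute] * math.pi * radius**2

    def landuse_proportion(self, class_code: str) -> float:
        """At the node site, sitting exactly on the half-plane split."""
        return 0.5 if class_code in self.landcover_split else 0.0

    def emission_in_buffer(self, radius: float) -> float:
        """Uniform per-cell field: c * pi r^2 / cell_area (region ⊇ buffer)."""
        return self.emission_per_cell * math.pi * radius**2 / self.emission_cell_size**2

    def ndvi_annual(self) -> tuple[float, float, float]:
        vals = np.array(self.ndvi_values)
        return float(vals.mean()), float(vals.min()), float(vals.max())

    def relative_elevation(self, direction: str, threshold: float) -> float | None:
        """Percent for the node site; None when no closed form applies."""
        if self.dem_profile == "flat":
            return 0.0
        if self.dem_profile == "half_plane":
            # east half is dem_step above the site; thresholds below the
            # step see exactly the eastern half of the ring
            return 50.0 if direction == "above" else 0.0
        return None


@dataclass
class Scene:
    spec: SceneSpec
    sites: list[MonitoringSite]
    bundle: LayerBundle
    ground_truth: GroundTruth
    emission_table: EmissionGridTable
    ndvi_stacks: dict[int, NdviStack]  # keyed by year


def _grid_lines(extent, spacing):
    xmin, ymin, xmax, ymax = extent
    xs = np.arange(math.ceil(xmin / spacing) * spacing, xmax + 1e-9, spacing)
    ys = np.arange(math.ceil(ymin / spacing) * spacing, ymax + 1e-9, spacing)
    vertical = [LineString([(x, ymin), (x, ymax)]) for x in xs]
    horizontal = [LineString([(xmin, y), (xmax, y)]) for y in ys]
    return list(xs), list(ys), vertical + horizontal


def _dem_values(spec, xs, ys, node_x, node_y, rng):
    if spec.dem_profile == "flat":
        return np.full((ys.size, xs.size), spec.dem_base)
    if spec.dem_profile == "ramp":
        return spec.dem_base + spec.dem_ramp_slope * (xs[None, :] - node_x) * np.ones(
            (ys.size, 1)
        )
    if spec.dem_profile == "half_plane":
        # keep the node site's own cell on the low side: the step sits at
        # the first cell edge east of the site's cell center
        c = spec.dem_cell_size
        site_center = xs[np.argmin(np.abs(xs - node_x))]
        east = (xs[None, :] > site_center + c / 2.0) * np.ones((ys.size, 1))
        return spec.dem_base + spec.dem_step * east
    return spec.dem_base + rng.normal(0.0, 10.0, size=(ys.size, xs.size))


def _ndvi_value(spec, year, composite_index):
    if spec.ndvi_profile == "constant":
        return spec.ndvi_constant
    # seasonal sinusoid peaking mid-year, clipped to the byte scale
    phase = 2.0 * math.pi * (composite_index + 0.5) / 36.0
    v = spec.ndvi_constant + spec.ndvi_amplitude * math.sin(phase - math.pi / 2.0)
    return float(np.clip(v, 0.0, 255.0))


def generate_scene(spec: SceneSpec) -> Scene:
    """Build all layers plus ground truth; deterministic in the spec."""
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = spec.extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0

    # --- roads: a regular grid; first site sits on the node nearest the center
    road_xs, road_ys, lines = _grid_lines(spec.extent, spec.road_grid_spacing)
    if not road_xs or not road_ys:
        raise GeocovError("road grid spacing leaves no roads inside the extent")
    node_x = float(min(road_xs, key=lambda x: abs(x - cx)))
    node_y = float(min(road_ys, key=lambda y: abs(y - cy)))
    types = sorted(ROAD_TYPES)
    roads = []
    for i, geom in enumerate(lines):
        road_type = types[i % len(types)]
        lanes = int(rng.choice(spec.lane_choices))
        is_highway = road_type in ("national_highway", "metro_city_highway")
        speed = float(rng.choice([50.0, 60.0, 80.0, 100.0]))
        roads.append(
            RoadSegment(
                segment_id=f"R{i:03d}",
                geometry=geom,
                road_type=road_type,
                lanes=lanes,
                speed_limit=speed,
                is_highway=is_highway,
            )
        )

    # --- sites: node site first, the rest random in the inner 60%
    sites = [MonitoringSite("S000", node_x, node_y, "urban_background")]
    margin_x, margin_y = 0.2 * (xmax - xmin), 0.2 * (ymax - ymin)
    for k in range(1, spec.n_sites):
        sites.append(
            MonitoringSite(
                f"S{k:03d}",
                float(rng.uniform(xmin + margin_x, xmax - margin_x)),
                float(rng.uniform(ymin + margin_y, ymax - margin_y)),
                "other",
            )
        )

    # --- census tessellation with uniform per-attribute densities
    densities = {
        name: spec.population_density * w for name, w in CENSUS_ATTRIBUTE_WEIGHTS.items()
    }
    cell = spec.census_cell_size
    census_feats = []
    n_cx = math.ceil((xmax - xmin) / cell)
    n_cy = math.ceil((ymax - ymin) / cell)
    for iy in range(n_cy):
        for ix in range(n_cx):
            x0, y0 = xmin + ix * cell, ymin + iy * cell
            geom = box(x0, y0, min(x0 + cell, xmax), min(y0 + cell, ymax))
            attrs = {"zone_id": f"J{iy:03d}_{ix:03d}"}
            attrs.update({k: d * geom.area for k, d in densities.items()})
            census_feats.append(Feature(f"J{iy:03d}_{ix:03d}", geom, attrs))
    census = ZonalPolygonLayer(census_feats, layer_kind="census")

    # --- land cover: half-plane split through the node site
    left, right = spec.landcover_split
    landcover = ZonalPolygonLayer(
        [
            Feature("L_left", box(xmin, ymin, node_x, ymax), {"class_code": left}),
            Feature("L_right", box(node_x, ymin, xmax, ymax), {"class_code": right}),
        ],
        layer_kind="landcover",
    )

    # --- districts (two halves) + constant monthly vehicle counts
    districts = ZonalPolygonLayer(
        [
            Feature("D0", box(xmin, ymin, cx, ymax), {"district_id": "D0"}),
            Feature("D1", box(cx, ymin, xmax, ymax), {"district_id": "D1"}),
        ],
        layer_kind="admin_district",
    )
    vehicles_monthly = pd.DataFrame(
        {
            "district_id": ["D0", "D1"],
            **{
                f"m{m:02d}": [spec.vehicles_monthly_count, spec.vehicles_monthly_count]
                for m in range(1, 13)
            },
        }
    )

    # --- urbanized area: the western half (some roads urban, some not)
    urbanized = ZonalPolygonLayer(
        [Feature("U0", box(xmin, ymin, cx, ymax), {})], layer_kind="urbanized_area"
    )

    # --- depots
    depots = {}
    for kind in ("rail_station", "subway_station", "bus_stop", "airport"):
        feats = [
            Feature(
                f"{kind}_{k}",
                Point(
                    float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax))
                ),
                {},
            )
            for k in range(spec.n_depots)
        ]
        depots[kind] = PointFeatureLayer(feats, kind=kind)
    port_feats = []
    for k in range(spec.n_ports):
        if k < spec.n_major_ports:
            vessels = float(spec.port_vessel_threshold + 1 + rng.integers(0, 40000))
        else:
            vessels = float(rng.integers(0, int(spec.port_vessel_threshold) + 1))
        port_feats.append(
            Feature(
                f"port_{k:02d}",
                Point(float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax))),
                {"vessels_per_year": vessels},
            )
        )
    depots["port"] = PointFeatureLayer(port_feats, kind="port")

    # --- physical geography: river line, coastline, derived border
    river_y = ymin + 0.75 * (ymax - ymin)
    rivers = [Feature("river_0", LineString([(xmin, river_y), (xmax, river_y)]), {})]
    coastline = [Feature("coast_0", LineString([(xmin, ymin), (xmax, ymin)]), {})]
    border = derive_border_line(districts, northern_fraction=0.05)

    # --- emissions: uniform field over the whole extent
    e_cell = spec.emission_cell_size
    cells = []
    per_source = spec.emission_per_cell / 3.0
    ex0 = math.floor(xmin / e_cell) * e_cell
    ey0 = math.floor(ymin / e_cell) * e_cell
    x = ex0
    while x < xmax:
        y = ey0
        while y < ymax:
            for pollutant in POLLUTANTS:
                for source in ("point", "line", "area"):
                    cells.append(EmissionCell(x, y, source, pollutant, per_source))
            y += e_cell
        x += e_cell
    emission_table = EmissionGridTable(cells, cell_size=e_cell)
    emissions = emission_cells_to_polygons(emission_table)

    # --- vegetation stacks for three years, 36 composites each
    n_nx = math.ceil((xmax - xmin) / spec.ndvi_cell_size)
    n_ny = math.ceil((ymax - ymin) / spec.ndvi_cell_size)
    stacks: dict[int, NdviStack] = {}
    current_values: list[float] = []
    for year in (2009, 2010, 2011):
        composites = []
        for k in range(36):
            d = date(year, 1, 1) + timedelta(days=10 * k)
            v = _ndvi_value(spec, year, k)
            if year == 2010:
                current_values.append(v)
            composites.append(
                (
                    d,
                    RasterGrid(
                        origin_x=xmin,
                        origin_y=ymin,
                        cell_size=spec.ndvi_cell_size,
                        values=np.full((n_ny, n_nx), v),
                    ),
                )
            )
        stacks[year] = NdviStack(composites)

    # --- DEM
    dc = spec.dem_cell_size
    n_dx = math.ceil((xmax - xmin) / dc)
    n_dy = math.ceil((ymax - ymin) / dc)
    dem_xs = xmin + (np.arange(n_dx) + 0.5) * dc
    dem_ys = ymin + (np.arange(n_dy) + 0.5) * dc
    dem = RasterGrid(
        origin_x=xmin,
        origin_y=ymin,
        cell_size=dc,
        values=_dem_values(spec, dem_xs, dem_ys, node_x, node_y, rng),
    )

    bundle = LayerBundle(
        roads=roads,
        urbanized=urbanized,
        census=census,
        landcover=landcover,
        districts=districts,
        emissions=emissions,
        depots=depots,
        rivers=rivers,
        coastline=coastline,
        border=border,
        dem=dem,
        ndvi_year=stacks[2010],
        ndvi_years=[stacks[2009], stacks[2010], stacks[2011]],
        vehicles_monthly=vehicles_monthly,
        width_table=WidthTable.default(),
        port_vessel_threshold=spec.port_vessel_threshold,
    )

    ground_truth = GroundTruth(
        node_site_id="S000",
        roads_through_node=2,
        road_grid_spacing=spec.road_grid_spacing,
        census_densities=densities,
        landcover_split=spec.landcover_split,
        emission_per_cell=spec.emission_per_cell,
        emission_cell_size=e_cell,
        ndvi_constant=spec.ndvi_constant if spec.ndvi_profile == "constant" else None,
        ndvi_values=tuple(current_values),
        dem_profile=spec.dem_profile,
        vehicles=spec.vehicles_monthly_count,
        river_y=river_y,
        coast_y=ymin,
    )
    return Scene(spec, sites, bundle, ground_truth, emission_table, stacks)


# ---------------------------------------------------------------------------
# Small random scenes for oracle-equivalence checks (no closed form:
# these are meant to be compared against independent numeric oracles).


def random_counts_layer(
    rng: np.random.Generator,
    extent: tuple[float, float, float, float],
    cell_size: float,
    attribute: str = "count",
    high: float = 100.0,
) -> ZonalPolygonLayer:
    """Rectangular tessellation with random per-cell counts (uniform
    density *within* each cell, varying across cells)."""
    xmin, ymin, xmax, ymax = extent
    feats = []
    n_x = math.ceil((xmax - xmin) / cell_size)
    n_y = math.ceil((ymax - ymin) / cell_size)
    for iy in range(n_y):
        for ix in range(n_x):
            x0, y0 = xmin + ix * cell_size, ymin + iy * cell_size
            geom = box(x0, y0, min(x0 + cell_size, xmax), min(y0 + cell_size, ymax))
            feats.append(
                Feature(
                    f"Z{iy:03d}_{ix:03d}", geom,
                    {attribute: float(rng.uniform(0.0, high))},
                )
            )
    return ZonalPolygonLayer(feats, layer_kind="census")


def random_road_segments(
    rng: np.random.Generator,
    extent: tuple[float, float, float, float],
    n_segments: int,
) -> list[RoadSegment]:
    """Random straight segments with random attributes."""
    xmin, ymin, xmax, ymax = extent
    types = sorted(ROAD_TYPES)
    segments = []
    for i in range(n_segments):
        x1, x2 = rng.uniform(xmin, xmax, 2)
        y1, y2 = rng.uniform(ymin, ymax, 2)
        if (x1, y1) == (x2, y2):
            x2 += 1.0
        road_type = types[int(rng.integers(0, len(types)))]
        segments.append(
            RoadSegment(
                segment_id=f"RR{i:03d}",
                geometry=LineString([(x1, y1), (x2, y2)]),
                road_type=road_type,
                lanes=int(rng.integers(1, 10)),
                speed_limit=float(rng.choice([50.0, 60.0, 80.0, 100.0])),
                is_highway=road_type in ("national_highway", "metro_city_highway"),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Perturbation: coherent rigid/scaling transforms for invariance testing.


def _transform_raster(grid: RasterGrid, kind: str, magnitude, center) -> RasterGrid:
    if kind == "translate":
        dx, dy = magnitude
        return replace(grid, origin_x=grid.origin_x + dx, origin_y=grid.origin_y + dy)
    if kind == "rescale":
        f = float(magnitude)
        return RasterGrid(
            origin_x=grid.origin_x * f,
            origin_y=grid.origin_y * f,
            cell_size=grid.cell_size * f,
            values=grid.values.copy(),
            nodata=grid.nodata,
        )
    # rotate by k*90 degrees about the scene center; the rotated grid must
    # itself be axis-aligned, so arbitrary angles are unsupported
    angle = float(magnitude) % 360.0
    if angle % 90.0 != 0.0:
        raise GeocovError("raster rotation only supports multiples of 90 degrees")
    k = int(angle // 90) % 4
    cx, cy = center
    a = math.radians(angle)
    cos_a, sin_a = round(math.cos(a)), round(math.sin(a))
    corners = [
        (grid.origin_x + dx * grid.n_cols * grid.cell_size,
         grid.origin_y + dy * grid.n_rows * grid.cell_size)
        for dx in (0, 1) for dy in (0, 1)
    ]
    rotated = [
        (cx + (x - cx) * cos_a - (y - cy) * sin_a,
         cy + (x - cx) * sin_a + (y - cy) * cos_a)
        for x, y in corners
    ]
    new_x = min(p[0] for p in rotated)
    new_y = min(p[1] for p in rotated)
    n_rows = grid.n_rows if k % 2 == 0 else grid.n_cols
    n_cols = grid.n_cols if k % 2 == 0 else grid.n_rows
    c = grid.cell_size
    xs = new_x + (np.arange(n_cols) + 0.5) * c
    ys = new_y + (np.arange(n_rows) + 0.5) * c
    # back-rotate each new cell center into the old grid and look it up;
    # exact for 90-degree multiples (centers map onto centers)
    x_old = cx + (xs[None, :] - cx) * cos_a + (ys[:, None] - cy) * sin_a
    y_old = cy - (xs[None, :] - cx) * sin_a + (ys[:, None] - cy) * cos_a
    j_old = np.clip(
        np.floor((x_old - grid.origin_x) / c).astype(int), 0, grid.n_cols - 1
    )
    i_old = np.clip(
        np.floor((y_old - grid.origin_y) / c).astype(int), 0, grid.n_rows - 1
    )
    return RasterGrid(
        origin_x=new_x, origin_y=new_y, cell_size=c,
        values=grid.values[i_old, j_old], nodata=grid.nodata,
    )


def _transform_geom(geom, kind, magnitude, center):
    if kind == "translate":
        dx, dy = magnitude
        return affinity.translate(geom, xoff=dx, yoff=dy)
    if kind == "rescale":
        f = float(magnitude)
        return affinity.scale(geom, xfact=f, yfact=f, origin=(0, 0))
    return affinity.rotate(geom, float(magnitude), origin=center)


def perturb_scene(scene: Scene, kind: str, magnitude) -> Scene:
    """Apply a coherent translate/rescale/rotate to every layer and site.

    ``magnitude``: (dx, dy) for translate, a scale factor for rescale, an
    angle in degrees (multiple of 90) for rotate. Attribute values
    (counts, emissions) are untouched; only geometry moves.
    """
    if kind not in ("translate", "rotate", "rescale"):
        raise GeocovError(f"unknown perturbation {kind!r}")
    xmin, ymin, xmax, ymax = scene.spec.extent
    center = ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)

    def g(geom):
        return _transform_geom(geom, kind, magnitude, center)

    def fmap(features):
        return [Feature(f.feature_id, g(f.geometry), dict(f.attributes)) for f in features]

    def zmap(layer):
        return ZonalPolygonLayer(fmap(layer.features), layer_kind=layer.layer_kind) if layer else None

    b = scene.bundle
    sites = []
    for s in scene.sites:
        p = g(Point(s.x, s.y))
        sites.append(MonitoringSite(s.site_id, p.x, p.y, s.site_type))
    roads = [
        RoadSegment(r.segment_id, g(r.geometry), r.road_type, r.lanes, r.speed_limit, r.is_highway)
        for r in (b.roads or [])
    ]
    depots = {
        k: PointFeatureLayer(fmap(v.features), kind=v.kind) for k, v in b.depots.items()
    }
    new_bundle = LayerBundle(
        roads=roads,
        urbanized=zmap(b.urbanized),
        census=zmap(b.census),
        landcover=zmap(b.landcover),
        districts=zmap(b.districts),
        emissions=zmap(b.emissions),
        depots=depots,
        rivers=fmap(b.rivers) if b.rivers else None,
        coastline=fmap(b.coastline) if b.coastline else None,
        border=g(b.border) if b.border is not None else None,
        dem=_transform_raster(b.dem, kind, magnitude, center) if b.dem else None,
        ndvi_year=b.ndvi_year,
        ndvi_years=b.ndvi_years,
        vehicles_monthly=b.vehicles_monthly,
        width_table=b.width_table,
        scheme=b.scheme,
        port_vessel_threshold=b.port_vessel_threshold,
        landcover_class_attribute=b.landcover_class_attribute,
        ring_width=b.ring_width,
    )
    if kind in ("translate", "rescale") and b.ndvi_year is not None:
        new_bundle.ndvi_year = NdviStack(
            [(d, _transform_raster(grid, kind, magnitude, center)) for d, grid in b.ndvi_year]
        )
        new_bundle.ndvi_years = [
            NdviStack([(d, _transform_raster(grid, kind, magnitude, center)) for d, grid in st])
            for st in (b.ndvi_years or [])
        ]
    return Scene(
        scene.spec, sites, new_bundle, scene.ground_truth, scene.emission_table,
        scene.ndvi_stacks,
    )
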