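"""End-to-end orchestration: evaluate a variable catalog at a site set.

Every (site, variable) cell is dispatched to the op named by the
variable's definition. Per-cell failures that mean "no data here" (site
outside a raster, empty target layer, site in no district) become
missing cells; configuration errors (uncovered width combination,
unknown attribute) abort the run naming the offending variable. Empty
buffer sums are 0, never missing — the two are kept distinct all the way
into the output CSV (missing = empty cell).
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from geocov.buffers import (
    areal_weighted_sum,
    buffer_road_sum,
    emission_buffer_sum,
    land_use_proportion,
)
from geocov.catalog import VariableDefinition
from geocov.errors import ConfigurationError, GeocovError, SchemaError
from geocov.model import (
    DEFAULT_SCHEME,
    MonitoringSite,
    NdviStack,
    PointFeatureLayer,
    RasterGrid,
    RoadClassScheme,
    RoadSegment,
    WidthTable,
    ZonalPolygonLayer,
    validate_sites,
)
from geocov.proximity import (
    classify_road,
    filter_major_ports,
    nearest_distance,
)
from geocov.rasters import (
    extract_cell_value,
    ndvi_august_median,
    ndvi_stack_summary,
    relative_elevation,
)

logger = logging.getLogger(__name__)


@dataclass
class LayerBundle:
    """Everything compute_covariates may need, loaded and CRS-consistent."""

    roads: Sequence[RoadSegment] | None = None
    urbanized: ZonalPolygonLayer | None = None
    census: ZonalPolygonLayer | None = None
    landcover: ZonalPolygonLayer | None = None
    districts: ZonalPolygonLayer | None = None
    emissions: ZonalPolygonLayer | None = None  # from emission_cells_to_polygons
    depots: Mapping[str, PointFeatureLayer] = field(default_factory=dict)
    rivers: object | None = None  # layer or geometry list
    coastline: object | None = None
    border: object | None = None  # pre-derived border polyline
    dem: RasterGrid | None = None
    ndvi_year: NdviStack | None = None
    ndvi_years: Sequence[NdviStack] | None = None  # previous/current/following
    vehicles_monthly: pd.DataFrame | None = None
    width_table: WidthTable | None = None
    scheme: RoadClassScheme = DEFAULT_SCHEME
    port_vessel_threshold: float = 10000.0
    landcover_class_attribute: str = "class_code"
    ring_width: float = 30.0


class CovariateTable:
    """Sites x variables result matrix (missing as NaN, distinct from 0)."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def to_wide_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index_label="site_id", lineterminator="\n")

    def to_long_csv(self, path: str | Path, catalog: Sequence[VariableDefinition]) -> None:
        by_name = {d.name: d for d in catalog}
        records = []
        for site_id, row in self.frame.iterrows():
            for name, value in row.items():
                d = by_name[name]
                records.append(
                    {
                        "site_id": site_id,
                        "category": d.category,
                        "variable": name,
                        "radius_m": d.parameters.get(
                            "radius", d.parameters.get("ring_radius", "")
                        ),
                        "value": value,
                    }
                )
        long = pd.DataFrame.from_records(records)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        long.to_csv(path, index=False, lineterminator="\n")


def vehicles_for_site(
    site: MonitoringSite,
    districts: ZonalPolygonLayer,
    monthly: pd.DataFrame,
    key: str = "district_id",
) -> float:
    """Annual mean of the 12 monthly vehicle counts of the district
    containing the site.

    A site on a shared boundary goes to the lowest district id
    (deterministic); a site in no district is missing (NaN).
    """
    month_cols = [c for c in monthly.columns if c != key]
    if key not in monthly.columns:
        raise SchemaError(f"monthly table missing key column {key!r}")
    by_id = monthly.set_index(monthly[key].astype(str))
    for _, row in by_id.iterrows():
        vals = row[month_cols]
        if len(vals) != 12:
            raise SchemaError(
                f"district {row[key]!r}: expected 12 month columns, got {len(vals)}"
            )
    pt = site.point
    candidates = sorted(
        (
            str(f.attributes.get(key, f.feature_id))
            for f in districts
            if f.geometry.covers(pt)
        ),
    )
    if not candidates:
        logger.warning("site %s lies in no district; vehicles missing", site.site_id)
        return math.nan
    district_id = candidates[0]
    if district_id not in by_id.index:
        logger.warning("district %r has no monthly row; vehicles missing", district_id)
        return math.nan
    return float(by_id.loc[district_id, month_cols].astype(float).mean())


def _roads_of_class(roads, road_class, scheme):
    if road_class == "ALL":
        return list(roads)
    return [s for s in roads if road_class in classify_road(s, scheme)]


def _evaluate(site: MonitoringSite, d: VariableDefinition, bundle: LayerBundle) -> float:
    p = dict(d.parameters)
    op = d.operation

    if op == "nearest_road_distance":
        subset = _roads_of_class(bundle.roads or [], p["road_class"], bundle.scheme)
        res = nearest_distance(site, subset, target=p["road_class"])
        return math.nan if res.is_missing else res.distance

    if op == "buffer_road_sum":
        return buffer_road_sum(
            site,
            p["radius"],
            bundle.roads or [],
            road_class=p["road_class"],
            weighting=p["weighting"],
            width_table=bundle.width_table,
            urbanized=bundle.urbanized,
            scheme=bundle.scheme,
        ).value

    if op == "vehicles_for_site":
        if bundle.districts is None or bundle.vehicles_monthly is None:
            return math.nan
        return vehicles_for_site(site, bundle.districts, bundle.vehicles_monthly)

    if op == "areal_weighted_sum":
        if bundle.census is None:
            return math.nan
        return areal_weighted_sum(site, p["radius"], bundle.census, p["attribute"]).value

    if op == "land_use_proportion":
        if bundle.landcover is None:
            return math.nan
        return land_use_proportion(
            site,
            p["radius"],
            bundle.landcover,
            p["class_code"],
            class_attribute=bundle.landcover_class_attribute,
        ).value

    if op == "nearest_depot_distance":
        layer = bundle.depots.get(p["kind"])
        if layer is None:
            return math.nan
        if p["kind"] == "port":
            layer = filter_major_ports(layer, bundle.port_vessel_threshold)
        res = nearest_distance(site, layer, target=p["kind"])
        return math.nan if res.is_missing else res.distance

    if op == "physical_distance":
        target = p["target"]
        layer = getattr(bundle, {"river": "rivers", "coastline": "coastline", "border": "border"}[target])
        if layer is None:
            return math.nan
        feats = layer if isinstance(layer, (list, ZonalPolygonLayer, PointFeatureLayer)) else [layer]
        res = nearest_distance(site, feats, target=target)
        return math.nan if res.is_missing else res.distance

    if op == "emission_buffer_sum":
        if bundle.emissions is None:
            return math.nan
        return emission_buffer_sum(site, p["radius"], bundle.emissions, p["pollutant"]).value

    if op == "ndvi_stack_summary":
        if bundle.ndvi_year is None:
            return math.nan
        summary = ndvi_stack_summary(site, bundle.ndvi_year)
        return getattr(summary, p["statistic"])

    if op == "ndvi_august_median":
        if not bundle.ndvi_years:
            return math.nan
        return ndvi_august_median(site, bundle.ndvi_years)

    if op == "extract_elevation":
        if bundle.dem is None:
            return math.nan
        return extract_cell_value(site, bundle.dem)

    if op == "relative_elevation":
        if bundle.dem is None:
            return math.nan
        return relative_elevation(
            site,
            bundle.dem,
            ring_radius=p["ring_radius"],
            threshold=p["threshold"],
            direction=p["direction"],
            ring_width=bundle.ring_width,
        ).proportion

    raise ConfigurationError(f"variable {d.name!r}: unknown operation {op!r}")


def compute_covariates(
    sites: Sequence[MonitoringSite],
    bundle: LayerBundle,
    catalog: Sequence[VariableDefinition],
) -> CovariateTable:
    """Evaluate every catalog variable at every site.

    Deterministic for identical inputs; rows are independent (site order
    only permutes rows). Configuration errors abort with the variable
    name; per-cell missing values do not.
    """
    validate_sites(sites)
    names = [d.name for d in catalog]
    data = np.full((len(sites), len(catalog)), np.nan)
    for j, d in enumerate(catalog):
        t0 = time.perf_counter()
        n_missing = 0
        for i, site in enumerate(sites):
            try:
                value = _evaluate(site, d, bundle)
            except (ConfigurationError, SchemaError) as exc:
                raise ConfigurationError(f"variable {d.name!r}: {exc}") from exc
            data[i, j] = value
            if isinstance(value, float) and math.isnan(value):
                n_missing += 1
        logger.info(
            "variable %s: %.3f s, %d/%d missing",
            d.name, time.perf_counter() - t0, n_missing, len(sites),
        )
    frame = pd.DataFrame(data, index=[s.site_id for s in sites], columns=names)
    return CovariateTable(frame)
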