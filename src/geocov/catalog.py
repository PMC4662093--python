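"""Declarative variable catalog.

Expands the eight covariate categories into a flat list of
:class:`VariableDefinition` from a small config: traffic distances and
road sums, areal-weighted census counts, land-use proportions, depot
distances, physical-geography distances, emission totals, vegetation
summaries, and altitude metrics. Variable names follow the template
``category.metric[.class][.<radius>m]`` and are unique within a catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from geocov.buffers import (
    EMISSION_RADII,
    NONTRAFFIC_RADII,
    RADII_PRESETS,
    TRAFFIC_RADII,
    WEIGHTINGS,
)
from geocov.errors import ConfigurationError
from geocov.model import LAND_USE_CLASSES, POLLUTANTS
from geocov.proximity import ROAD_CLASSES

#: Default census attribute breakdown: totals, housing by type and
#: construction era, companies/employees by the seven business classes.
#: The real source schema is configuration; this default is only a
#: plausible, internally consistent stand-in.
BUSINESS_CLASSES = (
    "agriculture",
    "manufacturing",
    "construction",
    "wholesale_retail",
    "lodging_restaurant",
    "transport",
    "services",
)

DEFAULT_CENSUS_ATTRIBUTES = (
    ("population_total", "households_total")
    + tuple(f"housing_{t}" for t in ("detached", "apartment", "rowhouse", "other"))
    + tuple(f"housing_built_{e}" for e in ("pre1990", "1990s", "2000s"))
    + tuple(f"companies_{b}" for b in BUSINESS_CLASSES)
    + tuple(f"employees_{b}" for b in BUSINESS_CLASSES)
)

DEPOT_KINDS = ("rail_station", "subway_station", "bus_stop", "airport", "port")

PHYSICAL_TARGETS = ("river", "coastline", "border")

DEFAULT_RINGS = (1000.0, 5000.0)
DEFAULT_THRESHOLDS = (20.0, 50.0)


@dataclass(frozen=True)
class VariableDefinition:
    name: str
    category: str
    operation: str
    parameters: Mapping[str, Any] = field(default_factory=dict)


def _radii(config: Mapping[str, Any], key: str, default: Sequence[float]) -> tuple[float, ...]:
    radii_cfg = config.get("radii", {})
    value = radii_cfg.get(key, default)
    if isinstance(value, str):
        if value not in RADII_PRESETS:
            raise ConfigurationError(f"unknown radii preset {value!r}")
        value = RADII_PRESETS[value]
    radii = tuple(float(r) for r in value)
    if any(r <= 0 for r in radii) or list(radii) != sorted(set(radii)):
        raise ConfigurationError(f"radii for {key!r} must be strictly increasing and > 0")
    return radii


def build_default_catalog(config: Mapping[str, Any] | None = None) -> list[VariableDefinition]:
    """Expand the full default variable taxonomy for a config.

    Recognized config keys: ``census_attributes`` (list; empty list means
    no demographic block), ``landuse_classes``, ``pollutants``,
    ``radii`` (dict with traffic/nontraffic/emission lists or preset
    names), ``rings``, ``thresholds``.
    """
    config = dict(config or {})
    defs: list[VariableDefinition] = []

    traffic_radii = _radii(config, "traffic", TRAFFIC_RADII)
    nontraffic_radii = _radii(config, "nontraffic", NONTRAFFIC_RADII)
    emission_radii = _radii(config, "emission", EMISSION_RADII)

    # --- traffic ---
    for cls in ROAD_CLASSES:
        defs.append(
            VariableDefinition(
                f"traffic.dist_road.{cls}", "traffic",
                "nearest_road_distance", {"road_class": cls},
            )
        )
    for cls in ROAD_CLASSES:
        for r in traffic_radii:
            for w in WEIGHTINGS:
                defs.append(
                    VariableDefinition(
                        f"traffic.road_sum.{cls}.{w}.{int(r)}m", "traffic",
                        "buffer_road_sum",
                        {"road_class": cls, "weighting": w, "radius": r},
                    )
                )
    defs.append(
        VariableDefinition(
            "traffic.registered_vehicles", "traffic", "vehicles_for_site", {}
        )
    )

    # --- demographic characteristics ---
    census_attributes = config.get("census_attributes", DEFAULT_CENSUS_ATTRIBUTES)
    for attr in census_attributes:
        if not isinstance(attr, str) or not attr:
            raise ConfigurationError(f"bad census attribute {attr!r}")
        for r in nontraffic_radii:
            defs.append(
                VariableDefinition(
                    f"demographic.{attr}.{int(r)}m", "demographic",
                    "areal_weighted_sum", {"attribute": attr, "radius": r},
                )
            )

    # --- land use ---
    landuse_classes = tuple(config.get("landuse_classes", LAND_USE_CLASSES))
    unknown = set(landuse_classes) - set(LAND_USE_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown land-use class(es) {sorted(unknown)}")
    for cls in landuse_classes:
        for r in nontraffic_radii:
            defs.append(
                VariableDefinition(
                    f"landuse.{cls}.{int(r)}m", "landuse",
                    "land_use_proportion", {"class_code": cls, "radius": r},
                )
            )

    # --- transportation facilities ---
    for kind in DEPOT_KINDS:
        defs.append(
            VariableDefinition(
                f"transport.dist_{kind}", "transport",
                "nearest_depot_distance", {"kind": kind},
            )
        )

    # --- physical geography ---
    for target in PHYSICAL_TARGETS:
        defs.append(
            VariableDefinition(
                f"physical.dist_{target}", "physical",
                "physical_distance", {"target": target},
            )
        )

    # --- emissions ---
    pollutants = tuple(config.get("pollutants", POLLUTANTS))
    unknown = set(pollutants) - set(POLLUTANTS)
    if unknown:
        raise ConfigurationError(f"unknown pollutant(s) {sorted(unknown)}")
    for p in pollutants:
        for r in emission_radii:
            defs.append(
                VariableDefinition(
                    f"emission.{p}.{int(r)}m", "emission",
                    "emission_buffer_sum", {"pollutant": p, "radius": r},
                )
            )

    # --- vegetation ---
    for stat in ("annual_mean", "annual_min", "annual_max"):
        defs.append(
            VariableDefinition(
                f"vegetation.ndvi_{stat}", "vegetation",
                "ndvi_stack_summary", {"statistic": stat},
            )
        )
    defs.append(
        VariableDefinition(
            "vegetation.ndvi_august_median", "vegetation", "ndvi_august_median", {}
        )
    )

    # --- altitude ---
    defs.append(
        VariableDefinition("altitude.elevation", "altitude", "extract_elevation", {})
    )
    rings = tuple(float(r) for r in config.get("rings", DEFAULT_RINGS))
    thresholds = tuple(float(t) for t in config.get("thresholds", DEFAULT_THRESHOLDS))
    for ring in rings:
        for thr in thresholds:
            for direction in ("above", "below"):
                defs.append(
                    VariableDefinition(
                        f"altitude.rel_elev.{int(ring)}m.{direction}.{int(thr)}m",
                        "altitude", "relative_elevation",
                        {"ring_radius": ring, "threshold": thr, "direction": direction},
                    )
                )

    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate variable names in catalog: {dupes}")
    return defs
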