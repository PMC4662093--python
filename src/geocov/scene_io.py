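"""Writing synthetic scenes to disk and loading a full layer bundle
from a single YAML config, so the CLI exercises the same file formats a
real deployment would (GeoJSON vectors, ASCII-grid rasters, CSV tables).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from geocov.buffers import emission_cells_to_polygons
from geocov.catalog import build_default_catalog
from geocov.io import (
    load_emission_table_csv,
    load_ndvi_manifest,
    load_raster_asc,
    load_sites_csv,
    load_vector_layer,
    load_width_table_csv,
    write_emission_table_csv,
    write_raster_asc,
    write_sites_csv,
    write_vector_layer,
    write_width_table_csv,
)
from geocov.model import RoadClassScheme
from geocov.pipeline import LayerBundle
from geocov.proximity import derive_border_line
from geocov.synthetic import Scene

DEPOT_KINDS = ("rail_station", "subway_station", "bus_stop", "airport", "port")


def write_scene(scene: Scene, outdir: str | Path) -> Path:
    """Write every layer of a scene in the pipeline's input formats and
    return the path of the generated config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = scene.bundle

    write_sites_csv(scene.sites, outdir / "sites.csv")
    write_vector_layer(list(b.roads), outdir / "roads.geojson")
    write_vector_layer(b.urbanized, outdir / "urbanized.geojson")
    write_vector_layer(b.census, outdir / "census.geojson")
    write_vector_layer(b.landcover, outdir / "landcover.geojson")
    write_vector_layer(b.districts, outdir / "districts.geojson")
    for kind in DEPOT_KINDS:
        write_vector_layer(b.depots[kind], outdir / f"{kind}s.geojson")
    write_vector_layer(b.rivers, outdir / "rivers.geojson")
    write_vector_layer(b.coastline, outdir / "coastline.geojson")
    write_emission_table_csv(scene.emission_table, outdir / "emissions.csv")
    write_raster_asc(b.dem, outdir / "dem.asc")
    b.vehicles_monthly.to_csv(outdir / "vehicles_monthly.csv", index=False, lineterminator="\n")
    write_width_table_csv(b.width_table, outdir / "width_table.csv")

    manifests = {}
    for year, stack in sorted(scene.ndvi_stacks.items()):
        rows = []
        for d, grid in stack:
            name = f"ndvi/{year}/{d.isoformat()}.asc"
            write_raster_asc(grid, outdir / name)
            rows.append({"date": d.isoformat(), "path": name})
        manifest = outdir / f"ndvi_{year}.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False, lineterminator="\n")
        manifests[year] = manifest.name

    years = sorted(manifests)
    config = {
        "layers": {
            "roads": "roads.geojson",
            "urbanized": "urbanized.geojson",
            "census": "census.geojson",
            "landcover": "landcover.geojson",
            "districts": "districts.geojson",
            "rivers": "rivers.geojson",
            "coastline": "coastline.geojson",
            "emissions": "emissions.csv",
            "dem": "dem.asc",
            **{kind: f"{kind}s.geojson" for kind in DEPOT_KINDS},
        },
        "ndvi_manifests": {
            "current": manifests[years[len(years) // 2]],
            "all": [manifests[y] for y in years],
        },
        "vehicles_monthly": "vehicles_monthly.csv",
        "width_table": "width_table.csv",
        "emission_cell_size": scene.spec.emission_cell_size,
        "port_vessel_threshold": scene.spec.port_vessel_threshold,
        "border_northern_fraction": 0.05,
        "mr1_types": sorted(b.scheme.mr1_types),
        "mr2_lane_threshold": b.scheme.mr2_lane_threshold,
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path


def load_config(config_path: str | Path) -> dict:
    with open(config_path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_bundle(config: dict, base: str | Path) -> LayerBundle:
    """Materialize a LayerBundle from a config dict; paths are resolved
    relative to ``base`` (normally the config file's directory)."""
    base = Path(base)
    layers = config.get("layers", {})
    invalid = config.get("invalid_polygons", "reject")

    def path(key):
        return base / layers[key] if key in layers else None

    def poly(key, kind):
        p = path(key)
        return (
            load_vector_layer(p, kind, invalid_polygons=invalid) if p else None
        )

    roads = load_vector_layer(path("roads"), "road") if path("roads") else None
    depots = {}
    for kind in DEPOT_KINDS:
        p = path(kind)
        if p:
            depots[kind] = load_vector_layer(p, kind)

    emissions = None
    if path("emissions"):
        table = load_emission_table_csv(
            path("emissions"), cell_size=float(config.get("emission_cell_size", 1000.0))
        )
        emissions = emission_cells_to_polygons(table)

    districts = poly("districts", "admin_district")
    border = None
    if districts is not None:
        border = derive_border_line(
            districts, northern_fraction=float(config.get("border_northern_fraction", 0.1))
        )

    ndvi_year = None
    ndvi_years = None
    manifests = config.get("ndvi_manifests", {})
    if manifests.get("current"):
        ndvi_year = load_ndvi_manifest(base / manifests["current"])
    if manifests.get("all"):
        ndvi_years = [load_ndvi_manifest(base / m) for m in manifests["all"]]

    scheme_kwargs = {}
    if "mr1_types" in config:
        scheme_kwargs["mr1_types"] = frozenset(config["mr1_types"])
    if "mr2_lane_threshold" in config:
        scheme_kwargs["mr2_lane_threshold"] = int(config["mr2_lane_threshold"])
    scheme = RoadClassScheme(**scheme_kwargs) if scheme_kwargs else RoadClassScheme()

    rivers_layer = None
    if path("rivers"):
        rivers_layer = _line_features(path("rivers"))
    coast_layer = None
    if path("coastline"):
        coast_layer = _line_features(path("coastline"))

    from geocov.io import load_width_table_csv as _lw
    from geocov.model import WidthTable

    width_table = (
        _lw(base / config["width_table"])
        if config.get("width_table")
        else WidthTable.default()
    )

    vehicles = (
        pd.read_csv(base / config["vehicles_monthly"])
        if config.get("vehicles_monthly")
        else None
    )

    return LayerBundle(
        roads=roads,
        urbanized=poly("urbanized", "urbanized_area"),
        census=poly("census", "census"),
        landcover=poly("landcover", "landcover"),
        districts=districts,
        emissions=emissions,
        depots=depots,
        rivers=rivers_layer,
        coastline=coast_layer,
        border=border,
        dem=load_raster_asc(path("dem")) if path("dem") else None,
        ndvi_year=ndvi_year,
        ndvi_years=ndvi_years,
        vehicles_monthly=vehicles,
        width_table=width_table,
        scheme=scheme,
        port_vessel_threshold=float(config.get("port_vessel_threshold", 10000.0)),
        landcover_class_attribute=config.get("landcover_class_attribute", "class_code"),
        ring_width=float(config.get("ring_width", 30.0)),
    )


def _line_features(p: Path):
    """Line layers carry no domain invariants beyond geometry; load raw."""
    import json

    from shapely.geometry import shape

    from geocov.model import Feature

    with open(p, encoding="utf-8") as fh:
        doc = json.load(fh)
    feats = []
    for i, raw in enumerate(doc.get("features", [])):
        fid = str(raw.get("id", i))
        feats.append(Feature(fid, shape(raw["geometry"]), dict(raw.get("properties") or {})))
    return feats


def load_sites(config: dict, base: str | Path, sites_path: str | Path | None = None):
    if sites_path is None:
        sites_path = Path(base) / config.get("sites", "sites.csv")
    return load_sites_csv(sites_path)


def catalog_from_config(config: dict):
    return build_default_catalog(config.get("catalog", {}))
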