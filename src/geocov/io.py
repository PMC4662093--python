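"""Reading and writing the pipeline's standard formats.

Vector layers travel as GeoJSON FeatureCollections, rasters as ESRI
ASCII grids (.asc), tables as UTF-8 CSV with a header row. Everything is
validated against the domain-type invariants at the loading boundary, and
any in-band CRS declaration must name a projected, meter-based system —
geographic (degree) coordinates are rejected with instructions to
reproject, which keeps all downstream geometry in one planar CRS.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

from geocov.errors import CrsError, JoinError, LayerValidationError, SchemaError
from geocov.model import (
    EmissionCell,
    EmissionGridTable,
    Feature,
    LayerKind,
    MonitoringSite,
    PointFeatureLayer,
    PointKind,
    RasterGrid,
    RoadSegment,
    WidthRow,
    WidthTable,
    validate_sites,
)

logger = logging.getLogger(__name__)

#: Substrings that identify a geographic (degree-based) CRS declaration.
_GEOGRAPHIC_MARKERS = ("4326", "wgs84", "wgs 84", "crs84", "epsg:4269", "degree")

ROAD_ATTRS = ("road_type", "lanes", "speed_limit", "is_highway")


def _check_projected_crs(obj: dict, path: str | Path) -> None:
    crs = obj.get("crs")
    if crs is None:
        return  # no declaration: trusted to be the shared projected CRS
    name = ""
    if isinstance(crs, dict):
        name = str(crs.get("properties", {}).get("name", ""))
    else:
        name = str(crs)
    if any(m in name.lower() for m in _GEOGRAPHIC_MARKERS):
        raise CrsError(
            f"{path}: geographic (degree-based) CRS {name!r}; reproject to a "
            "projected meter-based CRS before loading"
        )


def _read_feature_collection(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    _check_projected_crs(obj, path)
    return obj["features"]


def _feature_id(raw: dict, idx: int) -> str:
    if "id" in raw and raw["id"] is not None:
        return str(raw["id"])
    props = raw.get("properties") or {}
    for key in ("id", "feature_id", "fid"):
        if key in props and props[key] is not None:
            return str(props[key])
    return str(idx)


def load_vector_layer(
    path: str | Path,
    layer_kind: str,
    schema: Mapping[str, str] | None = None,
    invalid_polygons: str = "reject",
):
    """Load a GeoJSON layer as the domain type matching ``layer_kind``.

    ``layer_kind`` is a :class:`~geocov.model.LayerKind` value, a
    :class:`~geocov.model.PointKind` value, or ``"road"``. ``schema``
    optionally renames source attributes to the expected names
    (``{expected: source_name}``). ``invalid_polygons`` is ``"reject"``
    (default) or ``"repair"`` (apply make_valid).
    """
    raw_features = _read_feature_collection(path)
    schema = dict(schema or {})

    def attr(props: dict, name: str, fid: str):
        source = schema.get(name, name)
        if source not in props:
            raise SchemaError(f"{path}: feature {fid!r} missing attribute {source!r}")
        return props[source]

    if layer_kind == "road":
        segments = []
        for i, raw in enumerate(raw_features):
            fid = _feature_id(raw, i)
            geom = shape(raw["geometry"])
            if geom.geom_type not in ("LineString", "MultiLineString"):
                raise SchemaError(f"{path}: feature {fid!r} is not a polyline")
            props = raw.get("properties") or {}
            segments.append(
                RoadSegment(
                    segment_id=fid,
                    geometry=geom,
                    road_type=attr(props, "road_type", fid),
                    lanes=int(attr(props, "lanes", fid)),
                    speed_limit=float(attr(props, "speed_limit", fid)),
                    is_highway=bool(attr(props, "is_highway", fid)),
                )
            )
        return segments

    features = []
    for i, raw in enumerate(raw_features):
        fid = _feature_id(raw, i)
        geom = shape(raw["geometry"])
        props = dict(raw.get("properties") or {})
        props.pop("id", None)
        features.append(Feature(feature_id=fid, geometry=geom, attributes=props))

    if layer_kind in PointKind._value2member_map_:
        for f in features:
            if f.geometry.geom_type != "Point":
                raise SchemaError(f"{path}: feature {f.feature_id!r} is not a point")
        if layer_kind == "port":
            src = schema.get("vessels_per_year", "vessels_per_year")
            for f in features:
                if src not in f.attributes:
                    raise SchemaError(
                        f"{path}: port feature {f.feature_id!r} missing {src!r}"
                    )
                f.attributes["vessels_per_year"] = float(f.attributes.pop(src))
        return PointFeatureLayer(features, kind=layer_kind)

    if layer_kind in LayerKind._value2member_map_:
        from geocov.model import ZonalPolygonLayer

        for f in features:
            if f.geometry.geom_type not in ("Polygon", "MultiPolygon"):
                raise SchemaError(
                    f"{path}: feature {f.feature_id!r} is not a polygon"
                )
            if not f.geometry.is_valid:
                if invalid_polygons == "repair":
                    f.geometry = make_valid(f.geometry)
                    logger.warning("repaired invalid polygon %s in %s", f.feature_id, path)
                else:
                    raise LayerValidationError(
                        f"{path}: invalid polygon {f.feature_id!r} "
                        "(set invalid_polygons='repair' to fix automatically)"
                    )
        return ZonalPolygonLayer(features, layer_kind=layer_kind)

    raise SchemaError(f"unknown layer_kind {layer_kind!r}")


def write_vector_layer(layer, path: str | Path) -> None:
    """Write a layer (ZonalPolygonLayer, PointFeatureLayer, or a list of
    RoadSegment) as a GeoJSON FeatureCollection with full float precision."""
    feats = []
    if isinstance(layer, list) and layer and isinstance(layer[0], RoadSegment):
        for seg in layer:
            feats.append(
                {
                    "type": "Feature",
                    "id": seg.segment_id,
                    "geometry": mapping(seg.geometry),
                    "properties": {
                        "road_type": seg.road_type,
                        "lanes": seg.lanes,
                        "speed_limit": seg.speed_limit,
                        "is_highway": seg.is_highway,
                    },
                }
            )
    else:
        for f in layer:
            feats.append(
                {
                    "type": "Feature",
                    "id": f.feature_id,
                    "geometry": mapping(f.geometry),
                    "properties": f.attributes,
                }
            )
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, separators=(",", ":"), sort_keys=True)


def load_sites_csv(path: str | Path) -> list[MonitoringSite]:
    """Site list CSV with columns site_id, x, y, site_type."""
    df = pd.read_csv(path, dtype={"site_id": str})
    for col in ("site_id", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            MonitoringSite(
                site_id=row.site_id,
                x=float(row.x),
                y=float(row.y),
                site_type=getattr(row, "site_type", "other") or "other",
            )
        )
    validate_sites(sites)
    return sites


def write_sites_csv(sites: Sequence[MonitoringSite], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "x", "y", "site_type"])
        for s in sites:
            w.writerow([s.site_id, repr(float(s.x)), repr(float(s.y)), s.site_type.value])


def load_raster_asc(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid. File rows are stored north-to-south; the
    in-memory matrix is flipped to the bottom-up convention."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise SchemaError(f"{path}: ASCII grid header missing {req!r}")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(
            f"{path}: grid body shape {values.shape} does not match header"
        )
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values[::-1],  # top-down file -> bottom-up matrix
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster_asc(grid: RasterGrid, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {grid.nodata!r}\n")
        for row in grid.values[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def load_width_table_csv(path: str | Path) -> WidthTable:
    df = pd.read_csv(path)
    required = {"is_highway", "speed_min", "speed_max", "is_urban", "width_m"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: width table missing columns {sorted(missing)}")
    rows = [
        WidthRow(
            is_highway=bool(r.is_highway),
            speed_min=float(r.speed_min),
            speed_max=float(r.speed_max),
            is_urban=bool(r.is_urban),
            width_m=float(r.width_m),
        )
        for r in df.itertuples(index=False)
    ]
    return WidthTable(rows)


def write_width_table_csv(table: WidthTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["is_highway", "speed_min", "speed_max", "is_urban", "width_m"])
        for r in table.rows:
            w.writerow([r.is_highway, r.speed_min, r.speed_max, r.is_urban, r.width_m])


def load_emission_table_csv(path: str | Path, cell_size: float = 1000.0) -> EmissionGridTable:
    """Emission CSV: corner_x, corner_y, source, pollutant, estimate."""
    df = pd.read_csv(path)
    required = {"corner_x", "corner_y", "source", "pollutant", "estimate"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: emission table missing columns {sorted(missing)}")
    cells = [
        EmissionCell(
            corner_x=float(r.corner_x),
            corner_y=float(r.corner_y),
            source=str(r.source),
            pollutant=str(r.pollutant),
            estimate=float(r.estimate),
        )
        for r in df.itertuples(index=False)
    ]
    return EmissionGridTable(cells, cell_size=cell_size)


def write_emission_table_csv(table: EmissionGridTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["corner_x", "corner_y", "source", "pollutant", "estimate"])
        for c in table.cells:
            w.writerow([repr(c.corner_x), repr(c.corner_y), c.source, c.pollutant, repr(c.estimate)])


def join_table_to_layer(layer, table: pd.DataFrame, key: str):
    """1:1 join of a tabular file onto a polygon layer by a shared key.

    Matched polygons gain the table's numeric columns; unmatched polygons
    keep their geometry with the new columns flagged missing (None).
    Duplicate keys in the table or zero matches raise :class:`JoinError`.
    """
    from geocov.model import ZonalPolygonLayer

    if key not in table.columns:
        raise JoinError(f"key {key!r} not in table columns {list(table.columns)}")
    keyed = table.set_index(table[key].astype(str))
    if keyed.index.has_duplicates:
        dups = keyed.index[keyed.index.duplicated()].unique().tolist()
        raise JoinError(f"duplicate key(s) in table: {dups}")
    value_cols = [c for c in table.columns if c != key]

    n_matched = 0
    out = []
    for f in layer:
        layer_key = str(f.attributes.get(key, f.feature_id))
        attrs = dict(f.attributes)
        if layer_key in keyed.index:
            n_matched += 1
            for c in value_cols:
                attrs[c] = keyed.at[layer_key, c]
        else:
            for c in value_cols:
                attrs[c] = None
            logger.warning("join: no table row for polygon key %r", layer_key)
        out.append(Feature(f.feature_id, f.geometry, attrs))
    if n_matched == 0:
        raise JoinError(f"join on {key!r} matched 0 of {len(out)} polygons (wrong key?)")
    return ZonalPolygonLayer(out, layer_kind=layer.layer_kind)


def load_ndvi_manifest(path: str | Path):
    """Manifest CSV (date, path) describing a composite stack; paths are
    resolved relative to the manifest location. Returns an NdviStack."""
    from datetime import date as _date

    from geocov.model import NdviStack

    base = Path(path).parent
    df = pd.read_csv(path)
    for col in ("date", "path"):
        if col not in df.columns:
            raise SchemaError(f"{path}: manifest missing column {col!r}")
    composites = []
    for r in df.itertuples(index=False):
        d = _date.fromisoformat(str(r.date))
        composites.append((d, load_raster_asc(base / str(r.path))))
    return NdviStack(composites)
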