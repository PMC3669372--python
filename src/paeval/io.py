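"""File formats: ESRI ASCII grids, GeoJSON registers and layers, CSV tables.

Rasters travel as ESRI ASCII grids (plain text, square cells, nodata -1 by
convention here); vector data as GeoJSON with a companion attribute CSV
(columns ``site_id, iucn_category, establishment_year, reported_area_km2``).
"""
from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import mapping, shape

from .grid import FractionGrid, GridError, GridGeometry, LandUseSeries

DEFAULT_NODATA = -1.0

#: default WDPA-style attribute names -> canonical field names
DEFAULT_FIELD_MAP = {
    "site_id": "site_id",
    "iucn_category": "iucn_cat",
    "establishment_year": "status_yr",
    "reported_area_km2": "rep_area",
}


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------
def write_ascii_grid(
    path: str | Path,
    grid: FractionGrid,
    nodata: float = DEFAULT_NODATA,
    fmt: str = "%.6g",
) -> None:
    """Write one fraction grid as an ESRI ASCII raster (square cells only)."""
    g = grid.geom
    if not math.isclose(g.dx, g.dy, rel_tol=1e-12):
        raise GridError("ESRI ASCII grids require square cells (dx == dy)")
    values = np.where(grid.land_mask, grid.values, nodata)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0 - g.nrows * g.dy!r}\n"
        f"cellsize {g.dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_array(
    path: str | Path, crs: str = "planar"
) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII raster as raw values (nodata -> NaN) + geometry."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    try:
        nrows, ncols = int(header["nrows"]), int(header["ncols"])
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + nrows * cell
    except KeyError as exc:  # pragma: no cover - malformed input
        raise GridError(f"missing ASCII grid header key: {exc}") from exc
    if values.shape != (nrows, ncols):
        raise GridError(
            f"{path}: data shape {values.shape} != header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.where(values == nodata, np.nan, values)
    geom = GridGeometry(nrows, ncols, x0, y0, cell, cell, crs=crs)
    return values, geom


def read_ascii_grid(path: str | Path, year: int, crs: str = "planar") -> FractionGrid:
    """Read an ESRI ASCII raster into a :class:`FractionGrid`."""
    values, geom = read_ascii_array(path, crs=crs)
    return FractionGrid(year=year, values=values, geom=geom)


# ---------------------------------------------------------------------------
# Registers (GeoJSON + attribute CSV)
# ---------------------------------------------------------------------------
def _parse_year(raw: object) -> int | None:
    if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
        return None
    year = int(float(raw))
    return year if year > 0 else None  # WDPA uses 0 for unknown dates


def read_register(
    geojson_path: str | Path,
    field_map: Mapping[str, str] | None = None,
):
    """Read a protected-area register from GeoJSON.

    Attribute names are configurable via ``field_map`` (canonical -> file
    property name); defaults follow WDPA conventions (``iucn_cat``,
    ``status_yr``, ``rep_area``).  Returns a list of
    :class:`~paeval.pa_layers.SiteRecord`.
    """
    from .pa_layers import SiteRecord  # local import to avoid a cycle

    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    with open(geojson_path) as fh:
        collection = json.load(fh)
    records = []
    for i, feat in enumerate(collection.get("features", [])):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"]) if feat.get("geometry") else None
        site_id = str(props.get(fmap["site_id"], i))
        category = str(props.get(fmap["iucn_category"], "unknown") or "unknown")
        year = _parse_year(props.get(fmap["establishment_year"]))
        area_raw = props.get(fmap["reported_area_km2"])
        area = None if area_raw in (None, "") else float(area_raw)
        records.append(
            SiteRecord(
                site_id=site_id,
                geometry=geom,
                iucn_category=category,
                establishment_year=year,
                reported_area_km2=area,
            )
        )
    return records


def write_register(
    geojson_path: str | Path,
    records: Sequence,
    csv_path: str | Path | None = None,
) -> None:
    """Write a register as GeoJSON plus an optional attribute CSV."""
    features = []
    for rec in records:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(rec.geometry) if rec.geometry is not None else None,
                "properties": {
                    "site_id": rec.site_id,
                    "iucn_cat": rec.iucn_category,
                    "status_yr": rec.establishment_year,
                    "rep_area": rec.reported_area_km2,
                },
            }
        )
    with open(geojson_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["site_id", "iucn_category", "establishment_year", "reported_area_km2"]
            )
            for rec in records:
                writer.writerow(
                    [
                        rec.site_id,
                        rec.iucn_category,
                        rec.establishment_year if rec.establishment_year else "",
                        rec.reported_area_km2 if rec.reported_area_km2 is not None else "",
                    ]
                )


def write_layer(geojson_path: str | Path, layer) -> None:
    """Write a merged :class:`ProtectionLayer` as GeoJSON."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(part.geometry),
            "properties": {"strictest_category": part.category},
        }
        for part in layer.parts
    ]
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "reference_year": layer.reference_year,
            "total_area_km2": layer.total_area_km2,
        },
    }
    with open(geojson_path, "w") as fh:
        json.dump(payload, fh)


def load_series(
    paths: Sequence[str | Path], years: Sequence[int], crs: str = "planar"
) -> LandUseSeries:
    """Read a stack of ASCII grids as a :class:`LandUseSeries`."""
    if len(paths) != len(years):
        raise GridError("paths and years must align 1:1")
    return LandUseSeries(
        tuple(read_ascii_grid(p, year=y, crs=crs) for p, y in zip(paths, years))
    )
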