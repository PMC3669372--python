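"""Reduce land-cover inputs to converted-fraction grids.

Two input dialects are supported:

* categorical class rasters (GlobCover / GLC2000 style integer codes),
  reduced to binary converted/natural grids via a :class:`ClassMap`;
* fraction rasters (HYDE style per-cell percent of land converted), passed
  through with unit scaling and congruence checks.

The shipped class maps mark GlobCover codes 11, 14, 20, 30 and 190 and
GLC2000 codes 16-18 and 22 as converted habitat, everything else natural.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .grid import FractionGrid, GridError, GridGeometry, LandUseSeries

BUILTIN_CLASS_MAPS = {"globcover": "globcover_classes.csv", "glc2000": "glc2000_classes.csv"}


class ReclassifyError(ValueError):
    """Raised for invalid class rasters or class maps."""


@dataclass(frozen=True)
class ClassMap:
    """Binary converted/natural mapping for integer land-cover codes.

    Codes absent from the map default to ``natural`` (conservative: unmapped
    cover never inflates conversion estimates); ``strict=True`` errors on
    unmapped codes instead.
    """

    dataset_name: str
    status: Mapping[int, str]
    strict: bool = False

    def __post_init__(self) -> None:
        bad = {c: s for c, s in self.status.items() if s not in ("converted", "natural")}
        if bad:
            raise ReclassifyError(f"invalid status values in class map: {bad}")

    @classmethod
    def from_csv(cls, path: str | Path, dataset_name: str | None = None,
                 strict: bool = False) -> "ClassMap":
        status: dict[int, str] = {}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                code = int(row["code"])
                if code in status:
                    raise ReclassifyError(f"duplicate code {code} in {path}")
                status[code] = row["status"].strip()
        return cls(dataset_name or Path(path).stem, status, strict=strict)

    @classmethod
    def builtin(cls, name: str, strict: bool = False) -> "ClassMap":
        """Load a packaged class map (``"globcover"`` or ``"glc2000"``)."""
        try:
            fname = BUILTIN_CLASS_MAPS[name.lower()]
        except KeyError:
            raise ReclassifyError(
                f"no builtin class map {name!r}; have {sorted(BUILTIN_CLASS_MAPS)}"
            ) from None
        ref = resources.files("paeval.data").joinpath(fname)
        with resources.as_file(ref) as path:
            return cls.from_csv(path, dataset_name=name.lower(), strict=strict)

    def converted_codes(self) -> frozenset[int]:
        return frozenset(c for c, s in self.status.items() if s == "converted")


def reclassify(
    raster: np.ndarray,
    class_map: ClassMap,
    geom: GridGeometry,
    year: int,
    nodata: int | None = None,
) -> FractionGrid:
    """Map an integer class raster to a binary {0, 1} fraction grid.

    Converted codes become 1.0, natural and (non-strict) unmapped codes 0.0;
    ``nodata`` cells become NaN.  Fraction-valued rasters must not pass
    through here, so float input with non-integral values is an error.
    """
    arr = np.asarray(raster)
    if np.issubdtype(arr.dtype, np.floating):
        finite = arr[np.isfinite(arr)]
        if finite.size and not np.all(finite == np.round(finite)):
            raise ReclassifyError(
                "float-valued raster: fraction inputs must not be reclassified"
            )
        arr = np.where(np.isfinite(arr), arr, nodata if nodata is not None else -9999)
        arr = arr.astype(np.int64)
    if arr.shape != geom.shape:
        raise GridError(f"raster shape {arr.shape} != geometry shape {geom.shape}")

    nodata_mask = np.zeros(arr.shape, dtype=bool) if nodata is None else arr == nodata
    codes = np.unique(arr[~nodata_mask])
    unmapped = [int(c) for c in codes if int(c) not in class_map.status]
    if unmapped and class_map.strict:
        raise ReclassifyError(
            f"unmapped {class_map.dataset_name} codes in strict mode: {unmapped}"
        )
    converted = class_map.converted_codes()
    values = np.isin(arr, list(converted)).astype(float)
    values[nodata_mask] = np.nan
    return FractionGrid(year=year, values=values, geom=geom)


def fraction_series(
    arrays: Sequence[np.ndarray],
    years: Sequence[int],
    geom: GridGeometry,
    percent: bool = False,
) -> LandUseSeries:
    """Build a :class:`LandUseSeries` from in-memory fraction arrays.

    With ``percent=True``, values on the 0-100 scale are divided by 100.
    Values outside the declared range are an error listing offending cells.
    """
    if len(arrays) != len(years):
        raise GridError("arrays and years must align 1:1")
    grids = []
    hi = 100.0 if percent else 1.0
    for arr, year in zip(arrays, years):
        arr = np.asarray(arr, dtype=float)
        bad = np.argwhere(np.isfinite(arr) & ((arr < 0) | (arr > hi)))
        if len(bad):
            raise GridError(
                f"year {year}: values outside [0, {hi}] at cells "
                f"{bad[:10].tolist()}" + ("..." if len(bad) > 10 else "")
            )
        grids.append(FractionGrid(year=year, values=arr / hi if percent else arr,
                                  geom=geom))
    return LandUseSeries(tuple(grids))


def load_fraction_series(
    paths: Sequence[str | Path],
    years: Sequence[int],
    percent: bool = False,
    crs: str = "planar",
) -> LandUseSeries:
    """Read congruent fraction rasters (ASCII grids) into one series."""
    from .io import read_ascii_array

    if len(paths) != len(years):
        raise GridError("paths and years must align 1:1")
    raw = [read_ascii_array(p, crs=crs) for p in paths]
    geom = raw[0][1]
    for (_, g), y in zip(raw[1:], years[1:]):
        if not g.congruent(geom):
            raise GridError(f"grid for year {y} not congruent with first year")
    return fraction_series([vals for vals, _ in raw], years, geom, percent=percent)


def coarsen(grid: FractionGrid, factor: int) -> FractionGrid:
    """Aggregate to a coarser grid by land-area-weighted block means.

    Partial edge blocks are allowed; nodata cells are excluded from block
    weights.  Conserves total converted area exactly (up to float error).
    """
    if factor < 1:
        raise GridError("coarsen factor must be >= 1")
    if factor == 1:
        return grid.copy()
    g = grid.geom
    nr, nc = g.shape
    NR, NC = -(-nr // factor), -(-nc // factor)
    areas = g.cell_areas_km2() * grid.land_mask
    conv = np.where(grid.land_mask, grid.values, 0.0) * areas

    pad_r, pad_c = NR * factor - nr, NC * factor - nc
    areas = np.pad(areas, ((0, pad_r), (0, pad_c)))
    conv = np.pad(conv, ((0, pad_r), (0, pad_c)))
    block_area = areas.reshape(NR, factor, NC, factor).sum(axis=(1, 3))
    block_conv = conv.reshape(NR, factor, NC, factor).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(block_area > 0, block_conv / block_area, np.nan)
    coarse = GridGeometry(NR, NC, g.x0, g.y0, g.dx * factor, g.dy * factor, crs=g.crs)
    return FractionGrid(year=grid.year, values=values, geom=coarse)
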