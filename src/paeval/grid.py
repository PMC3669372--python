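"""Raster grid containers for converted-fraction landscapes.

A :class:`FractionGrid` holds one year's per-cell fraction of land
anthropogenically converted, on a regular grid described by a
:class:`GridGeometry`.  Two coordinate flavours are supported:

* ``"planar"`` — synthetic equal-area grids, coordinates and cell sizes in km;
* ``"geographic"`` — lon/lat degrees, with cell areas approximated as
  proportional to the cosine of the cell-centre latitude.

Nodata (sea or unobserved) cells are stored as NaN and excluded from every
area denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: km per degree of latitude (and of longitude at the equator).
KM_PER_DEGREE = 111.32

VALID_CRS = ("planar", "geographic")


class GridError(ValueError):
    """Raised for malformed or incongruent grids."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular, north-up, row-major grid.

    ``(x0, y0)`` is the *top-left* corner; row ``i``, column ``j`` covers the
    half-open box ``[x0 + j*dx, x0 + (j+1)*dx) x (y0 - (i+1)*dy, y0 - i*dy]``.
    """

    nrows: int
    ncols: int
    x0: float
    y0: float
    dx: float
    dy: float
    crs: str = "planar"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise GridError("grid dimensions must be >= 1")
        if self.dx <= 0 or self.dy <= 0:
            raise GridError("cell sizes must be positive")
        if self.crs not in VALID_CRS:
            raise GridError(f"unknown crs {self.crs!r}; expected one of {VALID_CRS}")

    # -- coordinates -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        return (
            self.x0,
            self.y0 - self.nrows * self.dy,
            self.x0 + self.ncols * self.dx,
            self.y0,
        )

    def x_edges(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.ncols + 1)

    def y_edges(self) -> np.ndarray:
        """Descending y edges, top edge first."""
        return self.y0 - self.dy * np.arange(self.nrows + 1)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(xc[ncols], yc[nrows]) cell-centre coordinates; yc descending."""
        xc = self.x0 + self.dx * (np.arange(self.ncols) + 0.5)
        yc = self.y0 - self.dy * (np.arange(self.nrows) + 0.5)
        return xc, yc

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell land-surface area, km², shape (nrows, ncols).

        Planar grids have uniform ``dx*dy`` (km²).  Geographic grids use the
        spherical approximation area ∝ cos(latitude of cell centre).
        """
        if self.crs == "planar":
            return np.full(self.shape, self.dx * self.dy)
        _, yc = self.cell_centres()
        row_area = (
            self.dx * KM_PER_DEGREE * self.dy * KM_PER_DEGREE * np.cos(np.deg2rad(yc))
        )
        return np.repeat(row_area[:, None], self.ncols, axis=1)

    def congruent(self, other: "GridGeometry", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(
                [self.x0, self.y0, self.dx, self.dy],
                [other.x0, other.y0, other.dx, other.dy],
                rtol=rtol,
                atol=rtol * max(self.dx, self.dy),
            )
        )


@dataclass
class FractionGrid:
    """Per-cell converted fraction in [0, 1] for one year; NaN = nodata."""

    year: int
    values: np.ndarray
    geom: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geom.shape:
            raise GridError(
                f"values shape {self.values.shape} != geometry shape {self.geom.shape}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere(
                np.isfinite(self.values) & ((self.values < 0) | (self.values > 1))
            )
            raise GridError(
                f"fraction values outside [0, 1] at cells {bad[:10].tolist()}"
                + ("..." if len(bad) > 10 else "")
            )

    @property
    def land_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def land_area_km2(self) -> float:
        return float(self.geom.cell_areas_km2()[self.land_mask].sum())

    def mean_converted_pct(self, region_mask: np.ndarray | None = None) -> float:
        """Area-weighted mean converted percentage over land (and mask)."""
        areas = self.geom.cell_areas_km2()
        m = self.land_mask if region_mask is None else (self.land_mask & region_mask)
        denom = areas[m].sum()
        if denom <= 0:
            raise GridError("no land cells in region")
        return float(100.0 * (self.values[m] * areas[m]).sum() / denom)

    def copy(self) -> "FractionGrid":
        return FractionGrid(self.year, self.values.copy(), self.geom)


@dataclass
class LandUseSeries:
    """Congruent decadal stack of :class:`FractionGrid`, years increasing."""

    grids: tuple[FractionGrid, ...]

    def __post_init__(self) -> None:
        self.grids = tuple(self.grids)
        if not self.grids:
            raise GridError("empty land-use series")
        g0 = self.grids[0]
        years = [g.year for g in self.grids]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise GridError(f"series years not strictly increasing: {years}")
        for g in self.grids[1:]:
            if not g.geom.congruent(g0.geom):
                raise GridError(f"grid for year {g.year} not congruent with {g0.year}")

    @property
    def years(self) -> list[int]:
        return [g.year for g in self.grids]

    @property
    def geom(self) -> GridGeometry:
        return self.grids[0].geom

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self) -> Iterator[FractionGrid]:
        return iter(self.grids)

    def grid_for(self, year: int) -> FractionGrid:
        for g in self.grids:
            if g.year == year:
                return g
        raise KeyError(f"no grid for year {year}")
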