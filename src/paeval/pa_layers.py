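"""Protected-area register filtering and merged protection layers.

The register is a list of :class:`SiteRecord` (WDPA-style: polygon or point
geometry, IUCN management category, establishment year, reported area).
Analyses restrict to the categories managed primarily for biodiversity
(Ia-IV), drop point-only records and sites smaller than the land-cover
resolution, and — for historical analyses — drop sites without an
establishment date or gazetted too recently for post-establishment rates to
be estimable.

Retained sites are merged into a single non-overlapping estate layer; where
sites overlap, the overlap is assigned the strictest (lowest-numbered) IUCN
category.  Historical estate layers are built per decade from the sites
established by each decade year.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform
from shapely.ops import unary_union

from .grid import KM_PER_DEGREE

#: IUCN categories ordered strictest first; "unknown" sorts last.
CATEGORY_ORDER = ("Ia", "Ib", "II", "III", "IV", "V", "VI", "unknown")
#: Categories managed primarily for biodiversity conservation.
BIODIVERSITY_CATEGORIES = frozenset({"Ia", "Ib", "II", "III", "IV"})

_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


class RegisterError(ValueError):
    """Raised for empty filter results or irreparable geometries."""


def category_rank(category: str) -> int:
    """Strictness rank (0 = strictest).  Unknown codes rank after VI."""
    return _RANK.get(category, _RANK["unknown"])


def _sinusoidal_km(x: np.ndarray, y: np.ndarray):
    # equal-area sinusoidal projection, degrees -> km
    return (np.asarray(x) * KM_PER_DEGREE * np.cos(np.deg2rad(np.asarray(y))),
            np.asarray(y) * KM_PER_DEGREE)


def geometry_area_km2(geometry: BaseGeometry, crs: str = "planar") -> float:
    """Area of a geometry in km².

    Planar geometries are assumed to be in km already; geographic ones are
    projected with an equal-area sinusoidal transform before measuring.
    """
    if geometry is None or geometry.is_empty:
        return 0.0
    if crs == "planar":
        return float(geometry.area)
    return float(shp_transform(_sinusoidal_km, geometry).area)


@dataclass
class SiteRecord:
    """One protected area as registered."""

    site_id: str
    geometry: Optional[BaseGeometry]
    iucn_category: str = "unknown"
    establishment_year: Optional[int] = None
    reported_area_km2: Optional[float] = None

    @property
    def is_point_only(self) -> bool:
        return self.geometry is None or self.geometry.geom_type in (
            "Point",
            "MultiPoint",
        )

    def area_km2(self, crs: str = "planar") -> float:
        """Area from geometry when present, else the reported area."""
        if self.geometry is not None and not self.is_point_only:
            return geometry_area_km2(self.geometry, crs)
        return float(self.reported_area_km2 or 0.0)

    def repaired_geometry(self) -> BaseGeometry:
        geom = self.geometry
        if geom is None:
            raise RegisterError(f"site {self.site_id}: no geometry to merge")
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            if not geom.is_valid or geom.is_empty:
                raise RegisterError(
                    f"site {self.site_id}: geometry invalid and not repairable"
                )
        return geom


@dataclass
class FilterReport:
    """Reconciliation of register filtering: every record dropped once."""

    input_count: int
    retained: int
    dropped_category: int = 0
    dropped_unknown_category: int = 0
    dropped_point_only: int = 0
    dropped_sub_minimum_area: int = 0
    dropped_missing_date: int = 0
    dropped_gazetted_after_cutoff: int = 0

    @property
    def dropped_total(self) -> int:
        return (
            self.dropped_category
            + self.dropped_unknown_category
            + self.dropped_point_only
            + self.dropped_sub_minimum_area
            + self.dropped_missing_date
            + self.dropped_gazetted_after_cutoff
        )

    def __post_init__(self) -> None:
        if self.retained + self.dropped_total != self.input_count:
            raise RegisterError(
                f"filter report does not reconcile: {self.retained} retained "
                f"+ {self.dropped_total} dropped != {self.input_count} input"
            )

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "retained": self.retained,
            "dropped": {
                "category": self.dropped_category,
                "unknown_category": self.dropped_unknown_category,
                "point_only": self.dropped_point_only,
                "sub_minimum_area": self.dropped_sub_minimum_area,
                "missing_date": self.dropped_missing_date,
                "gazetted_after_cutoff": self.dropped_gazetted_after_cutoff,
            },
        }


def filter_register(
    records: Sequence[SiteRecord],
    mode: str = "current",
    min_area_km2: float = 1.0,
    latest_gazettement_year: Optional[int] = None,
    crs: str = "planar",
) -> tuple[list[SiteRecord], FilterReport]:
    """Apply the register inclusion rules.

    Both modes retain only categories Ia-IV, drop point-only records and
    sites below ``min_area_km2`` (area measured from geometry when present).
    ``mode="historical"`` additionally drops records without an establishment
    date and, when ``latest_gazettement_year`` is given, records gazetted
    after it.  ``mode="current"`` keeps undated records: their presence in
    the register confirms establishment, and current-state summaries do not
    need a date.

    Each dropped record is counted under exactly one rule (the first that
    applies, in the order above).
    """
    if mode not in ("current", "historical"):
        raise ValueError(f"mode must be 'current' or 'historical', got {mode!r}")
    if min_area_km2 < 0:
        raise ValueError("min_area_km2 must be >= 0")
    if not records:
        raise RegisterError("empty register")

    counts = dict.fromkeys(
        (
            "category",
            "unknown_category",
            "point_only",
            "sub_minimum_area",
            "missing_date",
            "gazetted_after_cutoff",
        ),
        0,
    )
    kept: list[SiteRecord] = []
    for rec in records:
        if rec.iucn_category not in BIODIVERSITY_CATEGORIES:
            if rec.iucn_category in _RANK:
                counts["category"] += 1
            else:
                counts["unknown_category"] += 1
            continue
        if rec.is_point_only:
            counts["point_only"] += 1
            continue
        if rec.area_km2(crs) < min_area_km2:
            counts["sub_minimum_area"] += 1
            continue
        if mode == "historical":
            if rec.establishment_year is None:
                counts["missing_date"] += 1
                continue
            if (
                latest_gazettement_year is not None
                and rec.establishment_year > latest_gazettement_year
            ):
                counts["gazetted_after_cutoff"] += 1
                continue
        kept.append(rec)

    report = FilterReport(
        input_count=len(records),
        retained=len(kept),
        dropped_category=counts["category"],
        dropped_unknown_category=counts["unknown_category"],
        dropped_point_only=counts["point_only"],
        dropped_sub_minimum_area=counts["sub_minimum_area"],
        dropped_missing_date=counts["missing_date"],
        dropped_gazetted_after_cutoff=counts["gazetted_after_cutoff"],
    )
    if not kept:
        raise RegisterError(
            f"no records survive filtering ({report.as_dict()['dropped']})"
        )
    return kept, report


@dataclass(frozen=True)
class LayerPart:
    geometry: BaseGeometry
    category: str


@dataclass
class ProtectionLayer:
    """Merged, non-overlapping estate footprint for one reference year."""

    reference_year: Optional[int]
    parts: tuple[LayerPart, ...]
    crs: str = "planar"

    @property
    def union(self) -> BaseGeometry:
        return unary_union([p.geometry for p in self.parts])

    @property
    def is_empty(self) -> bool:
        return not self.parts or all(p.geometry.is_empty for p in self.parts)

    @property
    def total_area_km2(self) -> float:
        return sum(geometry_area_km2(p.geometry, self.crs) for p in self.parts)


def merge_layer(
    records: Sequence[SiteRecord],
    reference_year: Optional[int] = None,
    crs: str = "planar",
) -> ProtectionLayer:
    """Union filtered sites into one layer, overlaps taking the strictest
    category present.

    With ``reference_year`` set, only sites with a known establishment year
    ``<= reference_year`` enter the layer.
    """
    selected = [
        r
        for r in records
        if reference_year is None
        or (r.establishment_year is not None and r.establishment_year <= reference_year)
    ]
    # group repaired geometries by category, strictest first
    by_cat: dict[str, list[BaseGeometry]] = {}
    for rec in selected:
        by_cat.setdefault(rec.iucn_category, []).append(rec.repaired_geometry())

    parts: list[LayerPart] = []
    covered: BaseGeometry | None = None
    for cat in sorted(by_cat, key=category_rank):
        merged = unary_union(by_cat[cat])
        chunk = merged if covered is None else merged.difference(covered)
        if not chunk.is_empty:
            parts.append(LayerPart(geometry=chunk, category=cat))
        covered = merged if covered is None else unary_union([covered, merged])
    return ProtectionLayer(reference_year=reference_year, parts=tuple(parts), crs=crs)


def historical_layers(
    records: Sequence[SiteRecord],
    decades: Sequence[int],
    crs: str = "planar",
) -> list[ProtectionLayer]:
    """One merged layer per decade, containing sites established by then.

    ``records`` must already be historical-mode filtered (no missing dates).
    A site established in year Y first appears in the layer for the first
    decade year >= Y, so protection is never credited before it existed.
    """
    decades = list(decades)
    if any(b <= a for a, b in zip(decades, decades[1:])):
        raise ValueError(f"decades must be strictly increasing: {decades}")
    undated = [r.site_id for r in records if r.establishment_year is None]
    if undated:
        raise RegisterError(
            f"historical layers need dated records; missing dates: {undated[:5]}"
        )
    return [merge_layer(records, reference_year=d, crs=crs) for d in decades]
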