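"""Register filtering and merged protection layers."""
from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon, box

from paeval.pa_layers import (
    FilterReport,
    RegisterError,
    SiteRecord,
    category_rank,
    filter_register,
    geometry_area_km2,
    historical_layers,
    merge_layer,
)


def site(sid, geom, cat="II", year=1950, area=None):
    return SiteRecord(sid, geom, cat, year, area)


def square(x, y, side):
    return box(x, y, x + side, y + side)


class TestFilter:
    def test_current_mode_mixed_degeneracies(self):
        """2 points + 1 sub-minimum polygon drop; undated records stay."""
        records = (
            [site(f"p{i}", Point(i, i)) for i in range(2)]
            + [site("small", square(0, 0, 0.7))]  # 0.49 km² < 1
            + [site(f"ok{i}", square(10 * i, 0, 3), year=None if i == 0 else 1950)
               for i in range(7)]
        )
        kept, report = filter_register(records, "current", min_area_km2=1.0)
        assert len(kept) == 7
        assert report.dropped_point_only == 2
        assert report.dropped_sub_minimum_area == 1
        assert report.dropped_missing_date == 0

    def test_historical_mode_exclusion_arithmetic(self):
        """593 records, 5 undated, 27 late-gazetted -> 561 retained."""
        records = []
        for i in range(593):
            if i < 5:
                year = None
            elif i < 32:
                year = 1996
            else:
                year = 1860 + (i % 14) * 10
            records.append(site(f"s{i}", square(3 * i, 0, 2), year=year))
        kept, report = filter_register(
            records, "historical", latest_gazettement_year=1994
        )
        assert len(kept) == 561
        assert report.dropped_missing_date == 5
        assert report.dropped_gazetted_after_cutoff == 27
        # same register in current mode keeps the undated sites
        kept_cur, _ = filter_register(records, "current")
        assert len(kept_cur) == 593

    def test_all_non_biodiversity_categories_error(self):
        records = [site(f"s{i}", square(3 * i, 0, 2), cat="V") for i in range(4)]
        with pytest.raises(RegisterError, match="no records survive"):
            filter_register(records, "current")

    def test_unknown_category_counted_separately(self):
        records = [site("a", square(0, 0, 2)), site("b", square(5, 0, 2), cat="Zz")]
        kept, report = filter_register(records, "current")
        assert len(kept) == 1
        assert report.dropped_unknown_category == 1
        assert report.dropped_category == 0

    def test_area_from_geometry_overrides_reported(self):
        """A big reported area does not save a geometrically tiny site."""
        records = [site("tiny", square(0, 0, 0.5), area=100.0),
                   site("ok", square(5, 0, 2))]
        kept, report = filter_register(records, "current", min_area_km2=1.0)
        assert [r.site_id for r in kept] == ["ok"]
        assert report.dropped_sub_minimum_area == 1

    def test_report_must_reconcile(self):
        with pytest.raises(RegisterError, match="reconcile"):
            FilterReport(input_count=5, retained=3, dropped_category=1)


class TestMerge:
    def test_disjoint_union_area_adds(self):
        layer = merge_layer([site("a", square(0, 0, np.sqrt(10))),
                             site("b", square(20, 0, np.sqrt(10)))])
        assert layer.total_area_km2 == pytest.approx(20.0, rel=1e-12)

    def test_coincident_squares_take_strictest(self):
        sq = square(0, 0, 3)
        layer = merge_layer([site("a", sq, cat="II"), site("b", sq, cat="Ia")])
        assert len(layer.parts) == 1
        assert layer.parts[0].category == "Ia"
        assert layer.total_area_km2 == pytest.approx(9.0, rel=1e-12)

    def test_partial_overlap_area_and_category(self):
        """Two 10 km² squares overlapping by 4 km²: union 16, overlap
        carries the stricter category."""
        s = np.sqrt(10)
        a = box(0, 0, s, s)
        # slide so the overlap is 4 km²: overlap width = 4/s
        dx = s - 4 / s
        b = box(dx, 0, dx + s, s)
        layer = merge_layer([site("a", a, cat="IV"), site("b", b, cat="Ib")])
        assert layer.total_area_km2 == pytest.approx(16.0, rel=1e-9)
        strict_area = sum(
            geometry_area_km2(p.geometry) for p in layer.parts if p.category == "Ib"
        )
        assert strict_area == pytest.approx(10.0, rel=1e-9)  # full stricter square

    def test_idempotent_and_order_independent(self, rng):
        sites = [site(f"s{i}", square(rng.uniform(0, 40), rng.uniform(0, 40), 5),
                      cat=np.random.default_rng(i).choice(["Ia", "II", "IV"]))
                 for i in range(12)]
        layer = merge_layer(sites)
        relayer = merge_layer(
            [site(f"m{i}", p.geometry, cat=p.category) for i, p in
             enumerate(layer.parts)]
        )
        assert relayer.total_area_km2 == pytest.approx(layer.total_area_km2, rel=1e-9)
        shuffled = list(sites)[::-1]
        layer2 = merge_layer(shuffled)
        assert layer2.total_area_km2 == pytest.approx(layer.total_area_km2, rel=1e-12)
        assert layer.union.symmetric_difference(layer2.union).area < 1e-9

    def test_union_area_bounded_by_sum(self, rng):
        sites = [site(f"s{i}", square(rng.uniform(0, 20), rng.uniform(0, 20), 6))
                 for i in range(8)]
        layer = merge_layer(sites)
        total = sum(s.area_km2() for s in sites)
        assert layer.total_area_km2 <= total + 1e-9

    def test_parts_pairwise_disjoint(self, rng):
        sites = [site(f"s{i}", square(rng.uniform(0, 20), rng.uniform(0, 20), 6),
                      cat=["Ia", "II", "IV", "III"][i % 4]) for i in range(10)]
        layer = merge_layer(sites)
        for i, p in enumerate(layer.parts):
            for q in layer.parts[i + 1:]:
                assert p.geometry.intersection(q.geometry).area < 1e-9

    def test_irreparable_geometry_names_site(self):
        bad = SiteRecord("broken", None, "II", 1950)
        with pytest.raises(RegisterError, match="broken"):
            merge_layer([bad])

    def test_reference_year_excludes_later_sites(self):
        layer = merge_layer(
            [site("a", square(0, 0, 2), year=1900),
             site("b", square(10, 0, 2), year=1990)],
            reference_year=1950,
        )
        assert layer.total_area_km2 == pytest.approx(4.0)


class TestHistoricalLayers:
    decades = tuple(range(1880, 2001, 10))

    def test_membership_by_establishment_date(self):
        records = [site("a", square(0, 0, 2), year=1889),
                   site("b", square(10, 0, 2), year=1950)]
        layers = historical_layers(records, self.decades)
        areas = {la.reference_year: la.total_area_km2 for la in layers}
        assert areas[1880] == 0.0
        for d in range(1890, 1950, 10):
            assert areas[d] == pytest.approx(4.0)
        for d in range(1950, 2001, 10):
            assert areas[d] == pytest.approx(8.0)

    def test_round_up_convention(self):
        """A 1972 site first appears in the 1980 layer."""
        records = [site("a", square(0, 0, 2), year=1972)]
        layers = historical_layers(records, self.decades)
        areas = {la.reference_year: la.total_area_km2 for la in layers}
        assert areas[1970] == 0.0
        assert areas[1980] == pytest.approx(4.0)

    def test_all_future_sites_give_empty_layers(self):
        records = [site("a", square(0, 0, 2), year=2005)]
        layers = historical_layers(records, self.decades)
        assert all(la.is_empty for la in layers)

    def test_monotone_estate_growth(self, rng):
        records = [site(f"s{i}", square(rng.uniform(0, 50), rng.uniform(0, 50), 4),
                        year=int(rng.choice(range(1860, 2000, 10))))
                   for i in range(20)]
        layers = historical_layers(records, self.decades)
        areas = [la.total_area_km2 for la in layers]
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_64_fold_growth_scenario(self):
        """A register built so the estate grows 64-fold between 1950 and
        2000 reports exactly that ratio."""
        records = [site("seed", square(0, 0, 1), year=1940)]
        # add 63 unit squares after 1950, disjoint
        records += [site(f"g{i}", square(3 * (i + 1), 0, 1), year=1960)
                    for i in range(63)]
        layers = historical_layers(records, (1950, 2000))
        assert layers[1].total_area_km2 / layers[0].total_area_km2 == pytest.approx(64.0)

    def test_decades_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            historical_layers([site("a", square(0, 0, 2))], (1900, 1890))

    def test_undated_records_rejected(self):
        with pytest.raises(RegisterError, match="missing dates"):
            historical_layers([site("a", square(0, 0, 2), year=None)], (1900, 1910))


def test_category_rank_order():
    ranks = [category_rank(c) for c in ("Ia", "Ib", "II", "III", "IV", "V", "VI")]
    assert ranks == sorted(ranks)
    assert category_rank("whatever") > category_rank("VI")


def test_geographic_area_uses_equal_area_projection():
    """A 1°x1° cell at 60°N is about half the area of one at the equator."""
    eq = box(0, -0.5, 1, 0.5)
    north = box(0, 59.5, 1, 60.5)
    ratio = geometry_area_km2(north, "geographic") / geometry_area_km2(eq, "geographic")
    assert ratio == pytest.approx(0.5, abs=0.01)
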