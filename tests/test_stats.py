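"""SMA regression, slope comparison, pre/post rates and profiles."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paeval.stats import (
    StatsError,
    conversion_histogram,
    establishment_decade,
    gazettement_rates,
    paired_t,
    quantile_profile,
    size_scaling,
    sma_fit,
    sma_slope_test,
)


class TestSMAFit:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = sma_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.ci_low == pytest.approx(2.0)
        assert fit.ci_high == pytest.approx(2.0)

    def test_closed_form_identity_random(self, rng):
        """slope == sign(r) * sd(y)/sd(x), checked against a fully
        independent direct computation."""
        for _ in range(20):
            n = int(rng.integers(5, 80))
            x = rng.normal(size=n)
            y = rng.normal(size=n) * rng.uniform(0.1, 5) + rng.uniform(-2, 2) * x
            fit = sma_fit(x, y)
            # independent arithmetic: explicit sums
            mx, my = sum(x) / n, sum(y) / n
            sxx = sum((v - mx) ** 2 for v in x) / (n - 1)
            syy = sum((v - my) ** 2 for v in y) / (n - 1)
            sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
            expect = (1 if sxy >= 0 else -1) * np.sqrt(syy / sxx)
            assert fit.slope == pytest.approx(expect, rel=1e-12)
            assert fit.ci_low <= fit.slope <= fit.ci_high
            assert np.sign(fit.slope) == np.sign(fit.r) or fit.r == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_self_inverse_property(self, seed):
        """SMA is symmetric in x and y: slope(y~x) * slope(x~y) == 1."""
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 40))
        x = r.normal(size=n)
        y = r.normal(size=n)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        assert sma_fit(x, y).slope * sma_fit(y, x).slope == pytest.approx(1.0, rel=1e-10)

    def test_negative_correlation_negative_slope(self, rng):
        x = np.linspace(0, 1, 30)
        y = -3 * x + rng.normal(0, 0.05, 30)
        fit = sma_fit(x, y)
        assert fit.slope < 0 and fit.r < 0
        assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_errors(self):
        with pytest.raises(StatsError, match="n >= 3"):
            sma_fit([1, 2], [3, 4])
        with pytest.raises(StatsError, match="zero variance"):
            sma_fit([1, 1, 1], [1, 2, 3])


class TestSlopeTest:
    def test_duplicated_group_gives_p_one(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 2 * x + rng.normal(0, 1, 20)
        res = sma_slope_test(x, y, x, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_difference_detected(self, rng):
        x1 = rng.uniform(0, 10, 100)
        x2 = rng.uniform(0, 10, 100)
        res = sma_slope_test(x1, x1 + rng.normal(0, 0.1, 100),
                             x2, 3 * x2 + rng.normal(0, 0.1, 100))
        assert res.p_value < 0.001
        assert res.slope1 == pytest.approx(1.0, abs=0.05)
        assert res.slope2 == pytest.approx(3.0, abs=0.15)

    def test_common_slope_between_group_slopes(self, rng):
        x1 = rng.uniform(0, 10, 30)
        x2 = rng.uniform(0, 10, 30)
        res = sma_slope_test(x1, 1.5 * x1 + rng.normal(0, 1, 30),
                             x2, 2.0 * x2 + rng.normal(0, 1, 30))
        lo, hi = sorted((res.slope1, res.slope2))
        assert lo <= res.common_slope <= hi

    def test_iid_null_calibration(self):
        """Two groups from identical lines plus identical noise: the LR test
        rejects at the nominal 5% rate (binomial 95% band over 500 reps)."""
        r = np.random.default_rng(7)
        rej = 0
        for _ in range(500):
            x1, x2 = r.uniform(0, 10, 16), r.uniform(0, 10, 16)
            y1 = 2 + 1.5 * x1 + r.normal(0, 1.0, 16)
            y2 = 2 + 1.5 * x2 + r.normal(0, 1.0, 16)
            rej += sma_slope_test(x1, y1, x2, y2).p_value < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / 500)
        assert 0.05 - band <= rej / 500 <= 0.05 + band, f"rate {rej / 500}"

    def test_permutation_variant_seeded(self, rng):
        x1 = rng.uniform(0, 10, 15)
        x2 = rng.uniform(0, 10, 15)
        y1 = 2 * x1 + rng.normal(0, 1, 15)
        y2 = 2 * x2 + rng.normal(0, 1, 15)
        r1 = sma_slope_test(x1, y1, x2, y2, method="permutation",
                            n_permutations=199, rng=np.random.default_rng(1))
        r2 = sma_slope_test(x1, y1, x2, y2, method="permutation",
                            n_permutations=199, rng=np.random.default_rng(1))
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1


class TestGazettementRates:
    @staticmethod
    def _traj(site_id, years, pcts):
        return pd.DataFrame({"site_id": site_id, "year": years,
                             "pct_converted": pcts})

    def test_constant_rate(self):
        df = self._traj("a", [1900, 1910, 1920, 1930], [0, 10, 20, 30])
        rates, excl = gazettement_rates(df, {"a": 1920})
        assert excl == {}
        assert rates.pre_rate[0] == pytest.approx(10.0)
        assert rates.post_rate[0] == pytest.approx(10.0)
        assert rates.n_decades_pre[0] == 2
        assert rates.n_decades_post[0] == 1

    def test_flat_trajectory_zero_rates(self):
        df = self._traj("a", [1900, 1910, 1920], [5, 5, 5])
        rates, _ = gazettement_rates(df, {"a": 1910})
        assert rates.pre_rate[0] == 0.0
        assert rates.post_rate[0] == 0.0

    def test_establishment_decade_rounds_up(self):
        """Establishment 1912 -> decade 1920; that decade's increment is
        pre-gazettement."""
        df = self._traj("a", [1900, 1910, 1920, 1930], [0, 1, 5, 6])
        rates, _ = gazettement_rates(df, {"a": 1912})
        assert rates.establishment_decade[0] == 1920
        assert rates.pre_rate[0] == pytest.approx((1 + 4) / 2)
        assert rates.post_rate[0] == pytest.approx(1.0)

    def test_exclusions_reasoned(self):
        df = pd.concat([
            self._traj("no_post", [1900, 1910], [0, 5]),
            self._traj("no_pre", [1900, 1910], [0, 5]),
            self._traj("ok", [1900, 1910, 1920], [0, 5, 9]),
        ])
        rates, excl = gazettement_rates(
            df, {"no_post": 1910, "no_pre": 1890, "ok": 1910}
        )
        assert set(rates.site_id) == {"ok"}
        assert excl["no_post"] == "no post-gazettement decades"
        assert excl["no_pre"] == "no pre-gazettement decades"

    def test_establishment_decade_helper(self):
        years = (1900, 1910, 1920)
        assert establishment_decade(1905, years) == 1910
        assert establishment_decade(1910, years) == 1910
        assert establishment_decade(1925, years) is None


class TestPairedT:
    def test_textbook_formula_oracle(self, rng):
        pre = rng.normal(1.3, 0.8, 30)
        post = rng.normal(1.0, 0.8, 30)
        res = paired_t(pre, post)
        d = pre - post
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), 29)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)
        assert res.df == 29
        assert res.mean_difference == pytest.approx(d.mean())

    def test_constant_difference_errors(self):
        with pytest.raises(StatsError, match="zero variance"):
            paired_t([2.0, 4.0, 6.0], [1.0, 3.0, 5.0])

    def test_identical_vectors_error(self):
        with pytest.raises(StatsError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSizeScaling:
    def test_proportional_conversion_gives_unit_slope(self, rng):
        area = 10 ** rng.uniform(0, 3, 50)
        fit = size_scaling(area, np.full(50, 35.0))
        assert fit.fit.slope == pytest.approx(1.0, rel=1e-9)
        assert not fit.excludes_unity

    def test_declining_fraction_slope_below_unity(self, rng):
        area = 10 ** rng.uniform(0, 3, 200)
        pct = 100 * np.minimum(1.0, area ** -0.25 * 10 ** rng.normal(0, 0.05, 200))
        fit = size_scaling(area, pct)
        assert fit.fit.slope < 1
        assert fit.excludes_unity

    def test_zero_converted_sites_excluded(self, rng):
        area = 10 ** rng.uniform(0, 2, 10)
        pct = np.full(10, 20.0)
        pct[:3] = 0.0
        fit = size_scaling(area, pct)
        assert fit.n_excluded_zero == 3
        assert fit.fit.n == 7

    def test_too_few_sites_error(self):
        with pytest.raises(StatsError):
            size_scaling([10.0, 20.0], [5.0, 5.0])


class TestHistogramAndQuantiles:
    def test_example_bins(self):
        res = conversion_histogram([5.0, 15.0, 95.0])
        assert res.counts.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 1]

    def test_top_edge_closed(self):
        res = conversion_histogram([100.0] * 4)
        assert res.counts[-1] == 4
        assert res.n_over_half == 4

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=300))
    def test_counts_conserved(self, values):
        res = conversion_histogram(values)
        assert res.counts.sum() == len(values)

    def test_over_half_is_strict(self):
        assert conversion_histogram([50.0, 50.1]).n_over_half == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            conversion_histogram([-1.0])

    def test_quantile_equal_groups(self, rng):
        area = rng.uniform(1, 100, 22)
        prof = quantile_profile(area, rng.uniform(0, 100, 22), k=11)
        assert list(prof.n) == [2] * 11
        assert prof.mean_area_km2.is_monotonic_increasing

    def test_quantile_remainder_to_smallest_groups(self, rng):
        prof = quantile_profile(rng.uniform(1, 100, 25), rng.uniform(0, 100, 25),
                                k=11)
        assert list(prof.n) == [3, 3, 3] + [2] * 8

    def test_constant_pct_zero_se(self, rng):
        prof = quantile_profile(rng.uniform(1, 100, 22), np.full(22, 40.0), k=11)
        assert np.allclose(prof.mean_pct_converted, 40.0)
        assert np.allclose(prof.se_pct_converted, 0.0)

    def test_monotone_construction_recovered(self, rng):
        area = np.sort(rng.uniform(1, 1000, 66))
        pct = 100 - 90 * (np.argsort(np.argsort(area)) / 65)
        prof = quantile_profile(area, pct, k=11)
        means = prof.mean_pct_converted.to_numpy()
        assert all(b < a for a, b in zip(means, means[1:]))
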