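"""Effectiveness statistics: SMA regression, slope comparison, pre/post rates.

Standardised major axis (model II) regression is used throughout because
both variables (time-aggregated conversion percentages, log site areas)
carry error.  The slope is sign(r)·sd(y)/sd(x); its confidence interval uses
the standard F-based construction

    B = F(1, n-2; conf) * (1 - r^2) / (n - 2),    CI = slope * (sqrt(B+1) ∓ sqrt(B)).

Two groups are compared with the common-slope likelihood-ratio test: the SMA
residual axis u = y - b*x and fitted axis v = y + b*x are uncorrelated
exactly at the group's own SMA slope, so

    LR(b) = -sum_i (n_i - 2.5) * log(1 - r_uv,i(b)^2)

minimised over the common slope b is asymptotically chi-square with
(groups - 1) df under a shared slope (the n-2.5 factor is the usual
small-sample correction).  A label-permutation alternative is provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


# ---------------------------------------------------------------------------
# SMA regression
# ---------------------------------------------------------------------------
@dataclass
class SMAFit:
    """A standardised-major-axis line fit with confidence interval."""

    slope: float
    intercept: float
    r: float
    n: int
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    x_label: str = "x"
    y_label: str = "y"

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "n": self.n,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "confidence": self.confidence,
            "x": self.x_label,
            "y": self.y_label,
        }


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise StatsError(f"need n >= 3 points, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance in x or y")
    return x, y


def sma_fit(
    x: Sequence[float],
    y: Sequence[float],
    confidence: float = 0.95,
    x_label: str = "x",
    y_label: str = "y",
) -> SMAFit:
    """Fit a standardised major axis line to (x, y)."""
    x, y = _check_xy(np.asarray(x), np.asarray(y))
    n = len(x)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    r = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    B = sps.f.ppf(confidence, 1, n - 2) * (1.0 - r * r) / (n - 2)
    lo, hi = slope * (np.sqrt(B + 1.0) - np.sqrt(B)), slope * (np.sqrt(B + 1.0) + np.sqrt(B))
    ci_low, ci_high = (lo, hi) if lo <= hi else (hi, lo)
    return SMAFit(
        slope=slope,
        intercept=intercept,
        r=r,
        n=n,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        confidence=confidence,
        x_label=x_label,
        y_label=y_label,
    )


# ---------------------------------------------------------------------------
# Common-slope comparison
# ---------------------------------------------------------------------------
@dataclass
class SlopeComparison:
    statistic: float
    p_value: float
    slope1: float
    slope2: float
    common_slope: Optional[float] = None
    method: str = "likelihood-ratio"

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "slope1": self.slope1,
            "slope2": self.slope2,
            "common_slope": self.common_slope,
            "method": self.method,
        }


def _group_moments(x: np.ndarray, y: np.ndarray) -> tuple[int, float, float, float]:
    n = len(x)
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    return n, sxx, sxy, syy


def _neg_loglik_term(b: float, n: int, sxx: float, sxy: float, syy: float) -> float:
    # squared correlation between u = y - b x and v = y + b x
    num = syy - b * b * sxx
    den = (syy - 2 * b * sxy + b * b * sxx) * (syy + 2 * b * sxy + b * b * sxx)
    r2 = num * num / den if den > 0 else 1.0
    r2 = min(r2, 1.0 - 1e-300)
    return -(n - 2.5) * np.log1p(-r2)


def sma_slope_test(
    x1: Sequence[float],
    y1: Sequence[float],
    x2: Sequence[float],
    y2: Sequence[float],
    method: str = "lr",
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> SlopeComparison:
    """Test whether two groups share a common SMA slope.

    ``method="lr"`` is the likelihood-ratio statistic against chi-square
    (1 df).  ``method="permutation"`` permutes group labels of the (x, y)
    pairs and uses |log slope ratio| as the statistic (distribution-free;
    the rng used is the caller's responsibility to seed).
    """
    x1, y1 = _check_xy(np.asarray(x1), np.asarray(y1))
    x2, y2 = _check_xy(np.asarray(x2), np.asarray(y2))
    fit1, fit2 = sma_fit(x1, y1), sma_fit(x2, y2)

    if method == "lr":
        groups = [_group_moments(x1, y1), _group_moments(x2, y2)]

        def objective(log_b: float) -> float:
            b = np.exp(log_b)
            s = np.sign(fit1.slope) or 1.0
            return sum(_neg_loglik_term(s * b, *g) for g in groups)

        lo = np.log(min(abs(fit1.slope), abs(fit2.slope))) - 1e-9
        hi = np.log(max(abs(fit1.slope), abs(fit2.slope))) + 1e-9
        res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-12})
        statistic = float(res.fun)
        common = float(np.sign(fit1.slope) * np.exp(res.x))
        p = float(sps.chi2.sf(statistic, df=1))
        return SlopeComparison(statistic, p, fit1.slope, fit2.slope, common, "likelihood-ratio")

    if method == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        observed = abs(np.log(abs(fit1.slope) / abs(fit2.slope)))
        xs = np.concatenate([x1, x2])
        ys = np.concatenate([y1, y2])
        n1 = len(x1)
        count = 1  # observed included
        for _ in range(n_permutations):
            perm = rng.permutation(len(xs))
            a, b = perm[:n1], perm[n1:]
            try:
                f1 = sma_fit(xs[a], ys[a])
                f2 = sma_fit(xs[b], ys[b])
            except StatsError:
                count += 1
                continue
            if abs(np.log(abs(f1.slope) / abs(f2.slope))) >= observed - 1e-15:
                count += 1
        p = count / (n_permutations + 1)
        return SlopeComparison(observed, p, fit1.slope, fit2.slope, None, "permutation")

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Pre/post gazettement rates and the paired t-test
# ---------------------------------------------------------------------------
def establishment_decade(year: int, decade_years: Sequence[int]) -> Optional[int]:
    """First decade year >= the establishment year (None if past the series)."""
    for d in decade_years:
        if d >= year:
            return d
    return None


def gazettement_rates(
    per_site_traj: pd.DataFrame,
    establishment_years: dict[str, int],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-site conversion rates before and after gazettement.

    ``per_site_traj`` is long format (site_id, year, pct_converted).  The
    decadal increment ending at year t+10 counts as *pre* when t+10 is at or
    before the site's establishment decade (rounded up to the decade grid),
    and *post* after it — conversion during the establishment decade began
    largely before protection took force.  Rates are mean percentage points
    per decade.  Sites lacking a pre or post decade are excluded with a
    reason.
    """
    rows, excluded = [], {}
    for site_id, grp in per_site_traj.groupby("site_id", sort=True):
        est = establishment_years.get(str(site_id))
        if est is None:
            excluded[str(site_id)] = "no establishment year"
            continue
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        pct = grp["pct_converted"].to_numpy()
        if len(years) < 2:
            excluded[str(site_id)] = "trajectory too short"
            continue
        est_dec = establishment_decade(est, years)
        if est_dec is None:
            excluded[str(site_id)] = "established after series end"
            continue
        increments = np.diff(pct)
        end_years = years[1:]
        pre = increments[end_years <= est_dec]
        post = increments[end_years > est_dec]
        if len(pre) == 0:
            excluded[str(site_id)] = "no pre-gazettement decades"
            continue
        if len(post) == 0:
            excluded[str(site_id)] = "no post-gazettement decades"
            continue
        rows.append(
            {
                "site_id": str(site_id),
                "establishment_year": est,
                "establishment_decade": est_dec,
                "pre_rate": float(pre.mean()),
                "post_rate": float(post.mean()),
                "n_decades_pre": len(pre),
                "n_decades_post": len(post),
            }
        )
    cols = ["site_id", "establishment_year", "establishment_decade",
            "pre_rate", "post_rate", "n_decades_pre", "n_decades_post"]
    return pd.DataFrame(rows, columns=cols), excluded


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_value: float
    mean_difference: float

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p_value": self.p_value,
                "mean_difference": self.mean_difference}


def paired_t(pre: Sequence[float], post: Sequence[float]) -> PairedTestResult:
    """Classical two-sided paired t-test on (pre - post)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise StatsError("pre and post must be 1-D and equal length")
    if len(pre) < 2:
        raise StatsError("paired t needs at least 2 pairs")
    diff = pre - post
    if np.std(diff, ddof=1) == 0:
        raise StatsError("zero variance of paired differences; t undefined")
    res = sps.ttest_rel(pre, post)
    return PairedTestResult(
        t=float(res.statistic),
        df=int(len(pre) - 1),
        p_value=float(res.pvalue),
        mean_difference=float(diff.mean()),
    )


# ---------------------------------------------------------------------------
# Size scaling, histogram, quantile profile
# ---------------------------------------------------------------------------
@dataclass
class SizeScalingFit:
    fit: SMAFit
    n_excluded_zero: int

    @property
    def excludes_unity(self) -> bool:
        """True when the CI lies wholly below or above a slope of 1."""
        return self.fit.ci_high < 1.0 or self.fit.ci_low > 1.0

    def as_dict(self) -> dict:
        d = self.fit.as_dict()
        d["n_excluded_zero"] = self.n_excluded_zero
        d["excludes_unity"] = self.excludes_unity
        return d


def size_scaling(
    area_km2: Sequence[float],
    pct_converted: Sequence[float],
    confidence: float = 0.95,
) -> SizeScalingFit:
    """SMA fit of log10(converted area in a site) on log10(site area).

    A slope below 1 (CI excluding unity) means larger sites carry
    proportionally less converted land.  Sites with zero converted area are
    excluded from the log-log fit (no pseudo-count offset, which would
    distort the slope); the exclusion count is reported.
    """
    area = np.asarray(area_km2, dtype=float)
    pct = np.asarray(pct_converted, dtype=float)
    if area.shape != pct.shape:
        raise StatsError("area and pct vectors must align")
    if np.any(area <= 0):
        raise StatsError("site areas must be positive")
    converted = area * pct / 100.0
    usable = converted > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("size_scaling: excluded %d sites with zero converted area",
                    n_excluded)
    if usable.sum() < 3:
        raise StatsError("fewer than 3 sites with nonzero converted area")
    fit = sma_fit(
        np.log10(area[usable]),
        np.log10(converted[usable]),
        confidence=confidence,
        x_label="log10(site area km2)",
        y_label="log10(converted area km2)",
    )
    return SizeScalingFit(fit=fit, n_excluded_zero=n_excluded)


@dataclass
class HistogramResult:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_over_half: int

    def as_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "n_over_half": self.n_over_half,
        }


def conversion_histogram(
    per_site_pct: Sequence[float], bin_width: float = 10.0
) -> HistogramResult:
    """Counts of sites per conversion band [0,w), [w,2w) ... [100-w,100].

    The top bin is closed at 100.  Also reports how many sites have more
    than half their habitat converted.
    """
    pct = np.asarray(per_site_pct, dtype=float)
    if np.any(~np.isfinite(pct)) or np.any(pct < 0) or np.any(pct > 100):
        raise StatsError("per-site percentages must lie in [0, 100]")
    if not (0 < bin_width <= 100):
        raise StatsError("bin width must be in (0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(pct, bins=edges)  # last bin closed at 100
    return HistogramResult(bin_edges=edges, counts=counts,
                           n_over_half=int((pct > 50.0).sum()))


def quantile_profile(
    area_km2: Sequence[float],
    pct_converted: Sequence[float],
    k: int = 11,
    site_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean ± SE conversion per size quantile group.

    Sites are ranked by area (ties broken by stable site-id order) and split
    into k equal-count groups; when n is not divisible by k the remainder is
    spread over the smallest-area groups.
    """
    area = np.asarray(area_km2, dtype=float)
    pct = np.asarray(pct_converted, dtype=float)
    n = len(area)
    if k < 2:
        raise StatsError("need k >= 2 quantile groups")
    if n < k:
        raise StatsError(f"need at least k={k} sites, got {n}")
    ids = np.asarray(site_ids if site_ids is not None else np.arange(n).astype(str))
    order = np.lexsort((ids, area))  # stable tie-break on site id
    q, r = divmod(n, k)
    sizes = [q + 1 if g < r else q for g in range(k)]
    rows, start = [], 0
    for g, size in enumerate(sizes):
        sel = order[start:start + size]
        start += size
        vals = pct[sel]
        se = float(np.std(vals, ddof=1) / np.sqrt(size)) if size > 1 else 0.0
        rows.append(
            {
                "group": g + 1,
                "n": size,
                "mean_area_km2": float(area[sel].mean()),
                "mean_pct_converted": float(vals.mean()),
                "se_pct_converted": se,
            }
        )
    return pd.DataFrame(rows)
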