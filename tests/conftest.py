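"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: rectangle
coverage is computed with pure-numpy interval arithmetic, and zonal
percentages by explicit per-cell loops, so they can arbitrate the
shapely-based implementation.
"""
from __future__ import annotations

import numpy as np
import pytest

from paeval.grid import FractionGrid, GridGeometry


# ---------------------------------------------------------------------------
# Analytic rectangle oracles (independent of paeval.overlay)
# ---------------------------------------------------------------------------
def rect_coverage_oracle(rect: tuple[float, float, float, float],
                         geom: GridGeometry) -> np.ndarray:
    """Fraction of each cell covered by an axis-aligned rectangle,
    via 1-D interval overlaps (no shapely)."""
    xmin, ymin, xmax, ymax = rect
    xe, ye = geom.x_edges(), geom.y_edges()
    wx = np.clip(np.minimum(xmax, xe[1:]) - np.maximum(xmin, xe[:-1]), 0, None)
    wy = np.clip(np.minimum(ymax, ye[:-1]) - np.maximum(ymin, ye[1:]), 0, None)
    return np.outer(wy, wx) / (geom.dx * geom.dy)


def zonal_oracle(values: np.ndarray, cov: np.ndarray, areas: np.ndarray):
    """Inside/outside converted percentages by explicit per-cell loops."""
    num_in = den_in = num_out = den_out = 0.0
    nr, nc = values.shape
    for i in range(nr):
        for j in range(nc):
            if not np.isfinite(values[i, j]):
                continue
            a = areas[i, j]
            num_in += values[i, j] * cov[i, j] * a
            den_in += cov[i, j] * a
            num_out += values[i, j] * (1 - cov[i, j]) * a
            den_out += (1 - cov[i, j]) * a
    pct_in = 100.0 * num_in / den_in if den_in > 0 else None
    pct_out = 100.0 * num_out / den_out if den_out > 0 else None
    return pct_in, pct_out


def sample_disjoint_rects(geom: GridGeometry, n: int,
                          rng: np.random.Generator) -> list[tuple]:
    """n non-overlapping random rectangles, 0.5-8 cells on a side."""
    rects: list[tuple] = []
    xmin0, ymin0, xmax0, ymax0 = geom.bounds
    attempts = 0
    while len(rects) < n:
        attempts += 1
        if attempts > 10_000:  # pragma: no cover - sampling safeguard
            raise RuntimeError("could not place disjoint rectangles")
        w = rng.uniform(0.5, 8) * geom.dx
        h = rng.uniform(0.5, 8) * geom.dy
        x = rng.uniform(xmin0, xmax0 - w)
        y = rng.uniform(ymin0, ymax0 - h)
        cand = (x, y, x + w, y + h)
        if all(
            not (cand[0] < r[2] and r[0] < cand[2]
                 and cand[1] < r[3] and r[1] < cand[3])
            for r in rects
        ):
            rects.append(cand)
    return rects


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------
@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def geom10() -> GridGeometry:
    """10x10 planar grid of 8 km cells, top-left at (0, 80)."""
    return GridGeometry(10, 10, 0.0, 80.0, 8.0, 8.0)


@pytest.fixture()
def random_grid(geom10, rng) -> FractionGrid:
    return FractionGrid(2000, rng.random(geom10.shape), geom10)
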