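# Methods

`paeval` evaluates how well a protected-area (PA) estate has retained
natural habitat, using a *compare-to-everywhere* design: the converted
fraction of land inside the merged estate is contrasted with all land
outside it, both in the current state and as decadal trajectories, and with
a *compare-to-nearby-time* design: each site's conversion rate before
versus after its legal establishment (gazettement). Because the real
inputs (a continental PA register and decadal land-use reconstructions)
are too large for desk-scale verification, every stage is exercised on
synthetic landscapes with known ground truth; this note records the model,
the defaults, and the choices made where the design was genuinely open.

## The estate model

A register record carries a geometry (polygon, multipolygon or point), an
IUCN management category, an establishment year and a reported area.
Analyses restrict to categories Ia–IV (managed primarily for biodiversity),
drop point-only records and sites smaller than `min_area_km2` (default
1 km², the resolution floor of ~0.3–8 km land-cover rasters; area is
measured from the geometry when one exists, since reported areas are
unreliable). Historical analyses additionally drop records without an
establishment date and, with the default cutoff of 1994, sites gazetted too
recently for post-establishment rates to be estimable. Current-state
analyses keep undated records: presence in the register confirms
establishment. Every dropped record is counted under exactly one rule, and
the filter report must reconcile (`retained + dropped == input`).

Retained sites are unioned into a single non-overlapping layer; any point
covered by several sites takes the strictest category present, with
strictness ordered Ia < Ib < II < III < IV < V < VI (IUCN numbering; the
natural reading of "more strictly managed"). Historical layers are built
per decade from the sites established by each decade year; a site
established in 1972 first enters the 1980 layer — rounding *up* avoids
crediting protection before it existed. The same convention dates the
pre/post split: the establishment decade's increment counts as *pre*,
because conversion during that decade began largely before protection took
force. Boundaries are static from establishment; degazettement and
boundary change are out of scope.

## Overlay arithmetic

Grids are regular and north-up; a cell is the half-open box
`[x0+j·dx, x0+(j+1)·dx) × (y0−(i+1)·dy, y0−i·dy]`, with values giving the
fraction of the cell's land converted and NaN marking sea/nodata cells,
which are excluded from every numerator and denominator. Planar synthetic
grids have uniform cell area; geographic grids use area ∝ cos(latitude of
cell centre), and geographic polygon areas an equal-area sinusoidal
projection.

Zonal statistics use an exact *coverage field*: per cell, polygon∩cell area
divided by cell area (computed with shapely; an independent pure-numpy
rectangle oracle arbitrates it in the tests). Then

    pct_inside  = 100 · Σ f·cov·a / Σ cov·a,
    pct_outside = 100 · Σ f·(1−cov)·a / Σ (1−cov)·a,

which guarantees the conservation identity: inside + outside converted
area equals the regional converted total. Fractional coverage is the
default because at ~8 km cells many sites span less than one cell and
cell-centre membership would misallocate them; a `centre` mode is provided
for comparison. Estate-level statistics use the merged layer (overlaps
counted once); per-site statistics use each site's own footprint (a cell
may legitimately contribute to two overlapping sites). Per-site
trajectories keep the footprint fixed over time, so pre-gazettement decades
measure conversion of the land that later became protected. Undefined
ratios — an empty estate before the first establishment, or an estate
covering the whole region — are flagged explicitly (`None`), never
reported as zero.

## Statistics

Both variables in the regressions carry error, so line fits are
standardised major axis (SMA, model II): slope = sign(r)·sd(y)/sd(x),
intercept through the means, and the F-based confidence interval
`slope·(√(B+1) ∓ √B)` with `B = F(1, n−2; conf)·(1−r²)/(n−2)`. Trajectory
fits use time as the independent variable, rescaled to decades since the
series start for conditioning; slopes are percentage points per decade.

Two groups are compared with a common-slope likelihood-ratio test: at a
group's own SMA slope the residual axis `u = y − b·x` and fitted axis
`v = y + b·x` are exactly uncorrelated, so
`LR(b) = −Σᵢ (nᵢ−2.5)·log(1−r²_uv,i(b))`, minimised over `b`, is
asymptotically χ²(1) under a shared slope (the −2.5 is the standard
small-sample correction). Monte-Carlo checks in the test suite confirm
nominal type-I error on independent bivariate data and near-nominal CI
coverage at n = 16. A label-permutation alternative (999 shuffles, caller-
seeded) is provided since the choice of test is not canonical.

Size scaling fits log10(converted area within site) on log10(site area);
a CI wholly below 1 means larger sites carry proportionally less converted
land. Sites with zero converted area are excluded (counted, logged) rather
than offset with a pseudo-count, which would distort the slope. Pre/post
rates are means of consecutive decadal differences in a site's converted
percentage, split at the establishment decade; the paired t-test on
(pre − post) across sites is classical (df = sites − 1), with sites
weighted equally, treating individual protected areas as the analysis
units. Histograms use half-open 10-point bins with the top bin closed at
100; quantile profiles rank sites by area, break ties by site id, and
spread any remainder over the smallest-area groups.

## The synthetic landscape generator

The generator emulates a HYDE-style land-use reconstruction: decadal grids
(default 1850–2000) of per-cell converted fraction with spatially
autocorrelated, monotone growth. Each decade an exogenous regional demand
(`base_hazard`, expected fraction of land converted per decade) is
allocated across cells proportionally to

    w = accessibility · (1 + contagion·mean 4-neighbour conversion)
        · protection_multiplier (cell centre inside an established site)
        · lognormal cell-decade noise (sd 0.5),

normalised so the realised regional increment equals the demand, and
`f ← min(f + δ, 1)` (increments exceeding the remaining land are clamped
and logged). Demand-driven allocation — how agricultural-expansion
reconstructions actually work — keeps expected regional increments
constant, matching the near-linear historical conversion trajectories the
generator emulates, and makes the no-effect configuration
(`protection_multiplier = 1`, uniform placement) a true null for the
pre/post comparison: a hazard acting multiplicatively on the *remaining*
fraction would instead build a spurious systematic decline in rates into
every site's history. Reported grids add per-cell observation noise
(sd 0.04) emulating classification uncertainty; the noiseless state is
monotone per cell and kept in the ground truth.

Defaults and why: 120×120 cells of 8 km (a HYDE-scale window);
`base_hazard = 0.0175` and an initial field around 0.25 so the region runs
from about a quarter to about half converted over 15 decades, the range the
emulated reconstructions report; accessibility is a west–east gradient
`exp(g·(x_norm−½))` with g = 1 (≈ e-fold pressure range, a remoteness
proxy); contagion weight 0.5 (clearance spreads from cleared
neighbourhoods); 100 rectangular sites with log-uniform areas 10–2000 km²
(mean ≈ 375 km², matching registered-estate scale at this resolution);
placement bias 0.3 (sites mildly favour low-pressure land, as real estates
do); protection multiplier 0.5 in the demonstration; establishment years
uniform over interior decades; degeneracy counts (3 point-only, 2
sub-minimum, 1 undated) per 100 records, mirroring real register quirks.
Sites are axis-aligned rectangles so analytic coverage fractions exist as
test oracles. Register and landscape use separate rng streams derived from
the seed by fixed offsets, so each is independently reproducible;
identical config + seed gives bit-identical output, and the pipeline
manifest is byte-stable.

What the generator does *not* emulate: urbanisation (excluded from the
fraction definition), abandonment/reversion, demographic drivers, sub-cell
allocation structure, real coastlines (the synthetic region is all land),
and covariate structure suitable for matching estimators. Passing tests
therefore show the *machinery* is correct under known conditions, not that
the real-world estimates are unbiased — in particular the
compare-to-everywhere design inherits any placement bias in the real data.

## Calibration findings and known limitations

Monte-Carlo experiments over replicate null datasets (no protection
effect, uniform placement; 200 replicates of 100 sites × 16 decades on an
80×80 grid — sizes chosen to make the experiments cheap while keeping
site-count realistic) show:

* the paired pre/post t-test holds its nominal 5% size;
* the trajectory common-slope test does **not** (≈ 50% rejection at
  α = 0.05), even though the identical test is correctly calibrated on
  independent bivariate data. The failure is structural, not a bug:
  cumulative conversion curves carry integrated (random-walk) clearance
  noise, and the inside curve additionally drifts as the growing estate
  changes composition, so treating the 16 decadal points as independent
  observations understates slope uncertainty. Removing all spatial
  heterogeneity from the generator still leaves ≈ 20% rejection from the
  integrated noise alone. Conclusion: naive SMA slope comparison of
  decadal conversion trajectories materially overstates the evidence for
  (or against) a difference, and inference on such trajectories should be
  read descriptively. The corresponding acceptance check is left failing
  by design to record this.

Numerical conventions: zone areas below 1e-9 km² count as empty;
"non-overlapping" layer parts tolerate 1e-9 of relative overlap; per-site
percentages are clamped to [0, 100] against float rounding at the bounds;
manifests round floats to 10 digits for byte-stable reproduction.
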