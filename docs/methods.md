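# Methods

## The analysis

The pipeline reproduces a three-stage macroecological design on gridded
presence/absence data.

**Stage 1 — regionalize and partition.**  1°×1° cells are grouped into
regional blocks of ~250,000 km².  Because cell area shrinks with
cos(latitude), blocks are latitude bands of fixed height whose longitudinal
width is chosen per band so block area stays near the target (area per 1°
cell is `L²·cos(lat_mid)` with `L ≈ 111.195 km`).  Blocks are retained only
if they contribute at least 15 cells present in the occurrence grid and at
least 5 species pooled over those cells (gamma diversity); both thresholds
are configurable, and the cell threshold is read inclusively (≥ 15).
Within each retained region the multiple-site Sørensen dissimilarity and
its Simpson (turnover) and nestedness-resultant components are averaged
over 10 random subsamples of 15 cells, standardizing regions of different
size.  Cells with no species are dropped before sampling — the multiple-site
quantities are undefined on empty sites — and a region must keep ≥ 15
non-empty cells to be scored.  Species present in the region but absent
from a subsample simply do not contribute; nothing is renormalized.

**Stage 2 — breakpoints.**  Each response (the three beta components and
the environmental surfaces T_DIF, T_PRES, PET) is regressed on absolute
centroid latitude with a two-segment model.  The default is the continuous
broken stick `y ~ 1 + x + (x − bp)·1[x > bp]`; a discontinuous variant
(independent line per segment) exists for sensitivity analysis.  The
breakpoint is located by exhaustive search over integer candidates strictly
inside the observed range with at least `min_seg = 5` points per side,
minimizing residual standard error; ties — which occur systematically when
the data are purely linear — resolve to the smallest candidate, and
residual differences below 1e-9 of the response SD count as ties so float
fuzz cannot break the contract.  In both modes the residual SE and the
model comparison charge 4 parameters (two slopes, one intercept, and one
degree of freedom for the estimated breakpoint), giving
`F = ((RSS_lin − RSS_pw)/2)/(RSS_pw/(n−4))` on `(2, n−4)` df — 321 regions
yield the conventional `(2, 317)`.  When RSS_pw is zero to float precision
the comparison reports F = +inf with p = 0 (flagged `exact_fit`), unless the
linear RSS is also zero, in which case the stick adds nothing and F = 0,
p = 1.  Segment summaries are t-based means ± 95% CI split at `x ≤ bp`.

**Stage 3 — drivers.**  Associations between beta components and
environment use Pearson correlations whose *test* (not the coefficient) is
corrected for spatial autocorrelation: pairwise great-circle distances
between region centroids are cut into 10 equal-frequency classes, a
Moran-type autocorrelation estimate is computed per class for each
variable, the estimates fill n×n autocorrelation matrices A and B
(diagonal 1), and with the centering projector H the variance of r is
estimated as `v = tr(HAHB)/(tr(HA)·tr(HB))`, giving an effective sample
size `M̂ = 1 + 1/v` used as a (real-valued) t degrees-of-freedom `M̂ − 2`.
In the i.i.d. limit the class estimates vanish and M̂ → n, recovering the
classical test; `M̂ ≤ 2` is reported as an undefined test, never silently
patched.  Ten classes is the conventional default; the count is
configurable and recorded in the output.  Explained variation is split by
partial regressions: with joint and marginal R² values,
`unique_A = R²_AB − R²_B`, `unique_B = R²_AB − R²_A`,
`shared = R²_A + R²_B − R²_AB` (percent scale).  The identity
`unique_A + unique_B + shared = R²_AB` is exact by construction.  Negative
shared fractions (suppression) are reported as-is and flagged.  Predictor
groups may overlap or duplicate each other: the joint R² is computed from
the least-squares projection, which stays unique under rank deficiency,
while each group alone must be full rank.  A three-group
inclusion–exclusion extension serves Venn-style displays.  Group contrasts
(glaciated vs unglaciated regions poleward of the breakpoint) use the
two-sided Mann-Whitney U with mid-ranks (U = min(U₁, U₂), half-integers
possible under ties; exact enumeration when n₁·n₂ ≤ 400 and tie-free,
otherwise the tie- and continuity-corrected normal approximation), and
richness–beta associations use Spearman's rho with the t approximation on
n − 2 df.  Tests are two-sided throughout.

Everything downstream of a seed is deterministic: per-region resampling
draws from a stream keyed on (master seed, region id), so neither region
order nor adding regions perturbs existing results.

## The synthetic world

The generator emulates the *structure* the analysis is designed to detect,
not any real fauna: a world whose compositional variation is
replacement-dominated equatorward of a breakpoint latitude and slides into
nestedness dominance poleward of it, with a climate-history surface (T_DIF)
kinked at the same latitude and smooth contemporary surfaces (T_PRES, PET,
PREC) that are linear in |latitude|.

Species occupancy combines two layers.  A **local layer** tiles the extent
with small rectangles (2×2 cells by default); neighbouring tiles share no
species, so sampling across tiles yields high turnover.  Per-tile richness
is constant equatorward of the breakpoint and decays linearly to zero
across the poleward zone (`transition_deg`; the full zone depth by
default).  Counts are Bresenham-dithered along each tile row so the decay
is smooth in the regional average rather than a rounding staircase.  A
**widespread nested pool** (64 species per polar zone by default) places
species whose ranges extend from a species-specific onset latitude to the
polar edge and span a western longitudinal *prefix* of the extent; along
any row, eastern pool assemblages are subsets of western ones, so where the
local layer has faded the remaining dissimilarity is pure ordered species
loss.  Setting `transition_deg = 0` and `nested_prefix_classes = 1`
recovers a sharp regime switch in which every poleward range is a strict
truncation of the largest one (multiple-site turnover exactly 0).

Two geometry choices deserve justification.  *Regions are one degree tall
by default* (`band_height_deg = 1`, so ~1°×20° blocks at the equator): a
breakpoint can only be located at 1° precision if centroid latitudes sample
the axis at that resolution, and 5°-tall square-ish blocks quantize the
centroids so coarsely that every candidate between band centres ties.  The
paper-style square regions remain available via `band_height_deg`.
*The poleward transition is graded, not a cliff*: the continuous broken
stick — the model whose parameter count matches the conventional
`(2, n−4)` comparison — fits a kink, and a step response sends the
RSE-minimizing breakpoint far from the true discontinuity.  The default
pool size (64) was set so the pool's richness surplus grows on the same
scale as the local layer's turnover signal, making the β_SIM decline
quasi-linear and the kink identifiable exactly at the regime boundary;
this recovery is seed-independent in the noiseless world.

What the generator does **not** emulate: polygon range shapes (all ranges
are axis-aligned rectangles of 1° cells), realistic richness gradients
(cell richness *rises* poleward in the default world as the pool
accumulates, so the sign of richness–beta rank correlations is a property
of the stylization, not a target), spatially realistic climate fields, or
any coastline/ocean mask.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery on data with
known structure — not that any real assemblage follows this model.

Climate defaults: T_PRES 28 °C at the equator falling 0.45 °C/deg; T_DIF
intercept 2 °C with slopes 0.09 °C/deg equatorward and 0.24 °C/deg
poleward of the breakpoint (the magnitudes reported for glacial-to-present
temperature anomalies in the motivating analysis); T_PAST = T_PRES − T_DIF;
PET/PREC in mm-like units with smooth declines; optional Gaussian noise per
surface (defaults 0.3–0.5 °C, 40–80 units); elevation flat at 0 m except
inside configured mountain blocks, where cell elevations are drawn with the
block's SD (700–900 m defaults), inflating regional altitudinal variability
(the population SD over member cells; sample SD switchable).  Cells at
|lat| ≥ `glaciation_lat` (50° default) are flagged glaciated.  Each
stochastic component (climate noise, elevation, species-identity shuffling,
resampling) draws from its own stream keyed on the master seed, so adding
species never perturbs climate noise.

## Calibration simulations

Two method-level simulations are frozen into the acceptance machinery.

*Breakpoint recovery:* n = 321 latitudes uniform on [29, 45] — observations
concentrated in the band where the kink lives — with the broken stick
0.46 + 0.002·(x−37) below / 0.46 − 0.016·(x−37) above and Gaussian noise
calibrated so the piecewise fit attains r² ≈ 0.3.  Noiseless data return
breakpoint 37 exactly; under noise the search lands within ±2° in well
over 90% of 200 replicates.  With latitudes spread over the full 0–70°
range instead, the same noise level localizes the breakpoint far less
precisely (recovery near 55%) — sparse coverage near the kink, not the
search, is the limiting factor.

*Spatial-correlation calibration:* 100 centroids on a 10×10 grid at 2°
spacing, independent Gaussian fields with exponential covariance of
1000 km range.  The corrected test's empirical type-I error sits near the
nominal 5% (the naive n−2-df test rejects ~half the time), and on i.i.d.
fields the mean effective sample size is within a few percent of n.

## Numerical conventions and degenerate inputs

- All-identical sites: the multiple-site ratios are 0/0; defined as 0.
- Empty sites are rejected with an instruction to pre-filter, never
  silently dropped.
- Piecewise fits require ≥ 2 points per segment and a non-constant
  response; candidate sets respect `min_seg` on both sides.
- OLS rank deficiency raises an error naming the collinear columns — which
  noise-free synthetic worlds trigger systematically for {T_PRES, T_PAST}
  groups, so the pipeline logs and skips those variance partitions rather
  than aborting.
- Mann-Whitney switches from exact enumeration to the corrected normal
  approximation exactly at n₁·n₂ > 400 or the first tie.
- JSON output renders ±inf as strings and NaN as null.

## Problem sizes

The default synthetic study uses a 60°×80° extent (4,800 cells, ~4,000
species, ~190 retained regions); the oracle comparison uses 1,000 random
matrices up to 8×12; the calibration simulations use 200 (breakpoint) and
1,000 (correlation) replicates.  These sizes make every property measurable
with comfortable margins while the full test suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

- The equal-area blocking is latitude-banded, not a true equal-area map
  projection; block shape (not area) varies with latitude and with the
  1°-band default the blocks are strongly elongated.
- The breakpoint F-test is computed at the *searched* breakpoint; under a
  purely linear truth the selection makes it anticonservative, so a
  significant F should be read as "a kink fits better", not as a
  selection-corrected p-value.
- The Dutilleul-style correction estimates autocorrelation from the same
  data it corrects; with very few regions per distance class M̂ is noisy,
  and subsets with n < 10 are not tested at all.
- The nestedness component is the Sørensen-minus-Simpson remainder; it
  inherits any bias of the resampling standardization at small gamma.
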