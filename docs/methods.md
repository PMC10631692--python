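# Methods

This note records the models implemented in `ecosec`, the choices made
where the methodology was genuinely open, and what the synthetic test
conditions do and do not demonstrate.

## Index model

The assessment works on categorical land-use maps with six classes typical
of a tropical prefecture under plantation pressure: natural forest, rubber
plantation, tea garden, cultivated land, built-up land and water.

For each class *i* three structure metrics are computed from the rook
(4-connected) patch mosaic:

- fragmentation `C_i = n_i / A_i` — patches per unit class area;
- separation `S_i = (1/2) sqrt(n_i / A) (A / A_i)` — sparser, more
  scattered classes score higher;
- fractal dimension `D_i` — patch mean of `2 ln(P/4) / ln(A_p)` with
  perimeter `P` (exposed cell edges) and area `A_p` in cell units.
  Single-cell patches are assigned `D = 1` (the formula's `ln A_p = 0`
  denominator is degenerate, and a 1-cell square is the simplest shape).

The disturbance index is the linear combination
`E_i = a C_i + b S_i + c D_i` with `a + b + c = 1`, default
`(0.5, 0.3, 0.2)`: fragmentation is weighted heaviest, then separation.
Vulnerability `F_i` is an expert-scored constant per class (built-up 0.05,
forest 0.10, cultivated 0.14, water 0.19, tea 0.24, rubber 0.28 in the
bundled defaults — monoculture plantations replacing natural forest are the
most sensitive). The loss index is `R_i = E_i F_i`.

The factor-analytic form of vulnerability (with vegetation-coverage and
soil-erosion covariates) is deliberately not implemented: its covariate
inputs are not available in a land-use-only pipeline, and the constant
table is what prefecture-scale applications of this index family actually
use.

**Units.** Patch counting is unit-free; areas entering `C` and `S` are in
hm² (1 hm² = 10⁴ m²). This choice is what places `E` and the grid risk
index on the conventional scale where the five security grades break at
0.042 / 0.049 / 0.056 / 0.06 on a [0, 1] axis. Class areas are *reported*
in 10⁴ hm², the customary tabulation unit. Both scales are exposed as
parameters (`area_unit_hm2`), and the scale covariance of `C` and `S`
under unit changes is tested explicitly.

## Risk grid

The study area is tessellated into square fishnet cells (default 10 km)
anchored at the lower-left corner of the boundary's bounding box. Cells
intersecting the boundary are kept with their clipped in-boundary area;
cells with under 1% of a full cell inside the boundary are dropped as
slivers (threshold configurable). Per cell `k`,

    ERI_k = sum_i (A_ki / A_k) R_i

with raster cells assigned to fishnet cells by their center coordinates
and out-of-boundary raster cells excluded. ERI is therefore a convex
combination of the class loss indices — it can never exceed the largest
`R_i` present, and the area-weighted mean ERI is invariant to the fishnet
cell size.

Grades I–V (I = lowest risk = highest security) use fixed breakpoints by
default so different epochs are directly comparable; an exhaustive
dynamic-programming Jenks natural-breaks classifier is available for
data-driven schemes. Intervals are left-closed/right-open with the top
interval closed, so a value exactly on a breakpoint takes the higher
(riskier) grade.

## Geostatistics

The empirical semivariogram bins half mean squared differences by pair
separation into 12 equal-width bins up to half the maximum pairwise
distance by default; bins are `(lower, upper]` so a pair exactly on an
edge joins the lower bin. Spherical and exponential models are fitted by
pair-count-weighted least squares (bounded trust-region, five
deterministic starts to escape local minima). The exponential range is
reported as the *practical* range (95% of the sill), the convention of
mainstream GIS software; divide by 3 for the e-folding scale.

Ordinary kriging solves the standard semivariance system with a Lagrange
multiplier for every target, using all points as the neighborhood — the
intended point sets (a few hundred fishnet centers) are small enough that
search-radius heuristics would only add parameters. Duplicate sample
locations are averaged before solving (they make the system singular).
With a nugget-free model the predictor is exact at data points and its
variance is zero there; both properties are tested to 1e-9.

## Spatial autocorrelation

Global Moran's I uses the cross-product statistic with `S² = Σz²/n`
normalization; local Moran's I is the Anselin form `I_i = z_i/m₂ Σ_j w_ij
z_j`, which satisfies `Σ_i I_i = n·I` under row-standardized weights (the
identity is verified numerically). Contiguity defaults to rook on the
fishnet lattice with row standardization; queen is available. Inference is
reported two ways: the normality z-score, and seeded permutations (global:
full relabeling; local: conditional permutation holding the focal value
fixed), 999 draws and alpha 0.05 by default. Significant local units are
labeled HH/LL/LH/HL by the quadrant of (z, spatial lag); everything else is
"ns". A uniform field raises an error rather than returning a meaningless
statistic.

## Gravity-center migration

Each grade's center of gravity is the area-weighted mean of its cell (or
patch) centroids. Transfer distance between epochs is
`d = c sqrt(ΔX² + ΔY²)` with `c = 111.11` km/degree for geographic
coordinates (a crude equirectangular conversion, adequate at low
latitudes and documented as such) and `c = 1` for projected km. The
operative direction is the atan2 compass bearing (clockwise from north)
mapped to 8-wind labels by 45° sectors; the raw quadrant-offset
arctangent `arctg(ΔY/ΔX)` is reported alongside because older studies
print that form, whose sector convention is ambiguous when Δ signs are
mixed. An empty grade yields an absent-centroid marker, not a zero point.

## GM(1,1) grey forecast

Per fishnet cell, the positive ERI series over ≥ 4 epochs is cumulated
(AGO), the background series uses the adjacent-mean coefficient
`α_bg = 0.5` (the universal convention; configurable), and the development
coefficient `a` and grey input `b` solve the least-squares system
`x⁰(k) + a z¹(k) = b`. Forecasts follow
`x¹(t+1) = (x⁰(1) − b/a) e^{−at} + b/a` differenced back to the original
scale; the first fitted value anchors to the first observation exactly.
`|a| < 1e-12` falls back to linear accumulation (the exact limit), so
constant series are fixed points. Fit quality is reported as R² and RMSE
per cell. Cells with a non-positive value anywhere in their series are
skipped (grey models require positive data) and carried forward at their
last observed value so the forecast grid stays complete; the diagnostics
table flags them.

The forecast is applied per cell rather than to grade aggregates because
only the per-cell route yields forecast *maps* whose grades, transitions
and gravity tracks can be analyzed with the same machinery as observed
epochs; grade-area series can still be forecast by fitting `fit_gm11` to
the proportion table. Forecast epochs are abstract steps; mapping steps to
calendar years is left to the run configuration.

## Synthetic data

The generator produces the three kinds of ground-truthed input the
pipeline needs.

**Categorical rasters.** Each class gets an exact cell quota
(largest-remainder rounding) and `ceil(quota / (1 + clumping))` seed
cells. Classes are placed from rarest to most abundant; each grows from
its seeds by a priority queue whose priority is distance to the nearest
seed plus uniform noise of 1.5 cell widths — compact patches with rough
edges — and the most abundant class fills the remainder as the landscape
matrix. Pure random-priority (Eden) growth was rejected because competing
frontiers strand enclave pockets that fragment the matrix class and break
the monotone response of patch count to clumping. Realized fractions match
targets exactly up to quota rounding; with clumping 0 the seeds *are* the
class (salt-and-pepper).

**Epoch transitions.** Rules convert `from_code` cells to `to_code` with a
baseline probability, multiplied (and clipped at 1) for cells already
touching the destination class — frontier-style plantation expansion.
Updates are synchronous against the input raster.

**Random fields.** Point values are drawn exactly from a zero-mean
Gaussian field with the requested spherical/exponential variogram by
Cholesky factorization of the dense covariance matrix — exact but O(n³),
intended for n ≲ 2000.

All randomness flows from one integer seed through a `numpy.random.Generator`.

### What the demo emulates — and what it does not

`make_demo_dataset` writes a 4-epoch sequence (default 120 × 100 km at
1-km resolution) in which rubber and tea expand into forest and cultivated
land urbanizes, with class fractions loosely calibrated to a forest-
dominated prefecture (forest 76%, rubber 15.4%, tea 2.6%, cultivated 4.6%,
built-up 1%, water 0.4%) and an irregular pentagon boundary. This
exercises every pipeline stage with realistic magnitudes, but it does not
emulate classification error, topographic controls on conversion, or the
patch-size distributions of real Landsat-derived maps — passing tests show
the *machinery* is correct, not that any particular landscape will show a
particular trend.

### Recovery-experiment design

The variogram parameter-recovery test uses 400 points on a 200 × 200
domain for a range-30 field (domain ≈ 6–7 × range, needed for a single
realization to be approximately ergodic in its variogram) and 15 lag bins
to 3 × the range so the range is resolved by several bins. Under this
design the mean relative error of (sill, range) over 10 seeds is well
inside the 25% acceptance band for both families.

## Problem sizes and numerical notes

- Default pipeline scale: ~100–250 fishnet cells, rasters up to a few
  hundred thousand cells; the demo (12,000 raster cells, 112 fishnet
  cells, 199 permutations) runs the full pipeline in a few seconds.
- Kriging and field simulation are dense linear algebra; both are exact
  and appropriate below a few thousand points.
- Variogram fitting bounds: nugget ≤ 2×, partial sill ≤ 4× the empirical
  maximum, range ≤ 10× the maximum lag; a tiny diagonal jitter
  (1e-10 × sill) guards the field simulator's Cholesky factorization.
- Grade classification validates inputs against the scheme's [0, upper]
  domain rather than silently clipping; the grey forecaster is the one
  place forecasts are clipped into the scheme domain, since an
  extrapolated exponential can exceed it.

## Known limitations

- Two cells of the published class-metrics table are internally
  inconsistent with the index definitions (one disturbance value, one loss
  value); the package reproduces the arithmetic, not the typos, and the
  tests exclude exactly those cells.
- No anisotropy, co-kriging or universal kriging; no Getis–Ord statistics;
  no GM(2,1)/Verhulst variants; no Fragstats-breadth metric families
  (core area, contagion, edge density).
- The 111.11 km/degree conversion ignores the cos(latitude) contraction of
  longitude degrees; at ~22° N this overstates east–west distances by
  about 7%. It is kept for comparability and documented here.
- Published direction labels in migration tables of this index family can
  disagree with the printed displacement signs; `ecosec` reports the
  unambiguous atan2 bearing and leaves reconciling legacy conventions to
  the user.
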