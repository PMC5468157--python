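# Methods

This note documents the models, algorithms, defaults, and design choices in
`habshift`, in the order the pipeline runs them.

## Data model and conventions

All spatial data live on a single shared equal-area grid (`grid_model.Grid`):
row 0 at the north edge, column 0 at the west edge, coordinates and cell
size in kilometres, cell area exactly `cell_size_km²`. Point-in-cell tests
use half-open cells (a point on a cell's north or west edge belongs to that
cell). Nodata propagates: every derived layer is invalid wherever any input
is invalid. The package deliberately performs no reprojection or
resampling — inputs must already share the grid, and `assert_aligned`
rejects stacks that disagree in shape, cell size, or origin beyond a
relative tolerance of 1e-6. Supported formats are ESRI ASCII grids
(read/write, header keywords case-insensitive, `unit="m"` available for
metre-denominated files), `x,y` CSV point tables, and GeoJSON polygon
collections. GeoTIFF input is not supported.

## Synthetic landscape generator

The generator (`synthetic_landscape`) produces the statistical structure
the analysis assumes, not any real climatology:

* **Elevation**: 3200 m at the north edge falling to ~1200 m at the south,
  plus ridge noise (500 m amplitude), clipped to [200, 3800] m.
* **Temperature-like layers**: the first is an annual-mean analogue, driven
  almost entirely by a 6.5 °C/km lapse on elevation plus smooth noise
  (0.8 °C); later ones emulate range/seasonality summaries with weak (20 %)
  elevation coupling, their own west–east gradients, and larger noise.
* **Precipitation-like layers**: north–south and west–east gradients, an
  orographic term (+0.08 mm per m of elevation), smooth noise, strictly
  positive. The resulting default layer set is only weakly mutually
  correlated, like a bioclimatic set that has already survived a
  collinearity screen.
* **Future scenario**: temperature layers receive an additive field whose
  spatial mean is exactly `temperature_delta` (default +1.5 °C, the middle
  of a mid-range-pathway mid-century band); precipitation layers a
  multiplicative field with spatial mean exactly `precipitation_scale`
  (default 0.9). Both fields are exactly demeaned, so a null scenario
  (delta 0, scale 1) yields future layers bit-identical to current ones.
  Infrastructure densities (rivers, roads, settlements) have no future
  projection and are held identical between scenarios.
* **Forest mask**: an autocorrelated field thresholded at a quantile so
  coverage equals `forest_fraction` (default 0.6, within the 0.4–0.8 band
  the tests assert).
* **Autocorrelation** is obtained by Gaussian low-pass filtering of white
  noise (σ = half the configured range in cells), normalized to unit
  variance — O(cells) cost rather than exact Gaussian-process draws, which
  is adequate for testing purposes.

The **true suitability** surface is a logistic in linear + quadratic terms
of standardized climate layers plus a Gaussian elevation envelope. The
default truth is a strongly niche-structured montane specialist: a narrow
band of the lapse-coupled temperature layer (quadratic coefficient −12 on
the standardized scale), wetter-is-better precipitation (linear +2,
quadratic −1), a broad 600 m elevation envelope, intercept −0.5. The
standardization constants are frozen from the *current* layers so the
identical transform applies to the future scenario; warming therefore
pushes the thermal optimum upslope, which is the directional signature the
pipeline must recover. These choices were fixed once, as the generator's
definition of the study conditions.

What the generator does **not** emulate: the named bioclimatic variable
formulas, GCM downscaling, survey-effort geometry beyond the forest
target-group structure, land-cover change, or biotic interactions. Passing
tests therefore demonstrate the pipeline's correctness and its ability to
recover a known climate-driven niche — not performance on real survey data.

Occurrences are sampled from forest cells with probability proportional to
true suitability, with replacement (so repeated records per cell occur and
thinning stays meaningful), jittered uniformly within the cell. Reserves
are non-overlapping rectangles placed by bounded rejection sampling
(default 19, covering ~30 % of the extent).

## Occurrence preparation

Thinning keeps exactly one record per occupied cell, chosen uniformly at
random; points outside the extent are dropped and counted. Output order is
by (row, col), so the result is reproducible given the seed. The
target-group background (default 10,000 points) samples forest cells
uniformly with replacement — with replacement because small fixtures may
have fewer forest cells than requested points. Background cells are not
excluded from presence cells by default (the model contrasts presence
against the available landscape, not against absences); an `exclude` hook
exists for the alternative.

## Variable screening

Stage 1 computes Pearson correlations between layers **at the presence +
background points** (the data the model actually sees, rather than all
raster cells) and greedily eliminates one member of every pair with
|r| > 0.8: repeatedly take the worst-offending retained pair and drop its
lower-priority member; absent priorities, drop the member with the larger
mean |r| against all other retained layers, ties broken alphabetically.
This is deterministic and guarantees the retained set has no violating
pair. Zero-variance layers get undefined correlations and are flagged
rather than eliminated. Stage 2, after a first model fit on the retained
layers, keeps only variables whose permutation importance is ≥ 1 % (the
cutoff behind the original study's 13 → 9 reduction is unstated; 1 % is
configurable) and refits.

## Maxent engine

Features per continuous variable: linear, quadratic, and K forward +
K reverse hinges (default K = 4) with knots at background quantiles, all
scaled to [0, 1] by the background min/max, queries clamped to that range.
A background-constant variable contributes a degenerate all-zero feature
pair and a warning.

The fit maximizes `mean_presence[λ·f] − log Z_λ − Σ β_j|λ_j|` with
`Z_λ = Σ_background exp(λ·f)`, by cyclic coordinate ascent with
soft-thresholding in fixed feature order. Because every feature lies in
[0, 1], the per-coordinate second derivative of log Z (a variance of a
[0, 1] variable) is at most 1/4; using h = 1/4 as the quadratic majorizer
makes every update a guaranteed ascent step with no line search, and the
optimizer is fully deterministic. Convergence: relative change of the
penalized objective < 1e-7 (default), cap 5,000 cycles, warning with the
final gradient norm on non-convergence. Zero-background-variance features
are frozen at weight 0 (their gradient is constant, so L1 could not stop
them). Default penalties β_j = β × s_j/√n with s_j the feature's
background standard deviation, n the presence count, β = 1. With zero
features the fit returns the uniform distribution over the m background
points with entropy log m — the unconstrained maximum-entropy solution.

Raw output q sums to 1 over the background sample; the logistic output
p = e^H q/(1 + e^H q) (H = fitted entropy over the background) is strictly
increasing in q and maps a "typical" cell (q = e^(−H)) to 0.5.

Evaluation: AUC is the rank-sum probability that a random presence
outscores a random background point, ties counting ½. The max-SSS
threshold scans the distinct observed scores, counting a presence suitable
at score ≥ t and a background point rejected at score < t, and takes the
smallest maximizing t (retaining more habitat on ties). Replication
(default 15) draws independent 75/25 presence splits with a shared
background and feature expansion; the ensemble prediction is the cellwise
mean of the replicate logistic grids and the ensemble threshold the mean
of the per-replicate thresholds computed from *training* presence scores.
Permutation importance permutes each variable's raw values jointly across
the stacked presence + background points and reports the training-AUC
drop, floored at 0 and normalized to 100 %. Jackknife gains (with-only /
leave-one-out) share one feature expansion so per-feature penalties are
identical across the nested fits, which makes leave-one-out gain ≤ full
gain a guaranteed property.

## Habitat maps, patch filter, change, indicators

Binarization is inclusive (value ≥ threshold), and by default one shared
threshold — the ensemble mean max-SSS from the current-scenario fit — is
applied to both scenarios (whether the original analysis re-thresholded
the future projection is unstated; a per-scenario threshold is available).
Patches are connected components under 8-neighbour adjacency by default
(diagonal continuity should not split habitat; 4-neighbour available).

The patch filter removes a patch only if it is **both** smaller than
4 km² **and** farther than 0.5 km from every other retained patch — the
conjunction reading of the home-range/dispersal rule, since a small patch
adjoining a large one remains usable (the two-independent-filters reading
is available by passing `max_gap_km=inf`). The gap between patches is the
minimum cell-center distance minus one cell size, floored at 0, so
orthogonally or diagonally adjacent cells read as gap 0. Removal is
iterated to a fixed point because removing a patch can isolate another; a
lone patch has infinite gap. Applying the filter to its own output changes
nothing.

Change classification is cellwise over the jointly valid domain:
(S,S) unchanged, (S,U) vulnerable, (U,S) new, (U,U) unsuitable; the four
categories partition the valid domain exactly. Indicators follow from the
category areas: A_c = unchanged + vulnerable, A_f = unchanged + new,
A_fc = unchanged; AC, SH_c, SH_f per the formulas in the README, reported
as undefined (None/"—") when a denominator is zero. (Note: the published
SH_f of 15.89 % is not reproducible from the published areas — the formula
on 4,529 and 3,823 km² gives 15.59 %, which is what the package reports.)

The elevation contrast takes one elevation value per suitable cell (not
per-patch means) and runs a two-sided Mann–Whitney test: the z statistic
uses the tie-corrected normal approximation with a 0.5 continuity
correction toward the mean; the p-value comes from exact enumeration of
group assignments (tie-safe) whenever C(n1+n2, n1) ≤ 20,000 and from z
otherwise. Full enumeration, rather than an n1·n2 rule, is the practical
bound: the arrangement count, not the product, governs feasibility.

## Reserve gap analysis

Reserves are rasterized by the cell-center rule (a cell belongs to the
first listed polygon containing its center), which keeps every reported
area an exact multiple of the cell area. Per-reserve suitable areas and
AC = (future − current)/current × 100 follow directly; reserves with zero
current area report "—". Network protection percentages use the union of
all reserve cells, so overlapping polygons are never double counted, and
the result is invariant to reserve order and to splitting a polygon.

The published per-reserve table and scenario areas ship as package data
and are used two ways: fed directly through `reserve_change`, and rebuilt
as an actual raster fixture (0.1 km cells, since the printed areas are
exact multiples of 0.01 km²; the geometry is synthetic, only the areas are
faithful) so the overlay code path itself reproduces the printed columns
and the network percentages.

## Pipeline, problem sizes, determinism

`run_pipeline` executes landscape → prep → screen → first model →
importance refit → 15-replicate ensemble → thresholding → patch filter →
change map → indicators → elevation contrast → reserve overlay, writing
every intermediate and a JSON + Markdown report embedding the config hash.
All randomness derives from the single config seed (stage seeds are fixed
offsets), so identical configs give byte-identical reports.

Default problem sizes — a 100×100 km landscape at 1 km, 273 occurrences,
10,000 background points, 15 replicates — run in ~10 s on one CPU; the
verification suite uses 200 presences and 5,000 background points for its
multi-seed recovery and directionality checks, a size chosen to keep
multi-seed experiments desk-scale while leaving the statistical behaviour
of the full-size problem intact.

## Known limitations

* Feature classes are linear/quadratic/hinge only — no product, threshold,
  or categorical features (hinge subsumes threshold in practice).
* No clamping/extrapolation diagnostics (MESS-style) for projection beyond
  the background range; queries are silently clamped.
* Single scenario pair; no multi-GCM/multi-pathway ensembles, no dispersal
  constraints, no corridor delineation.
* The greedy correlation screen does not guarantee a maximum-size retained
  set in pathological correlation structures (the tests check it against
  exhaustive search on small instances).
* Reprojection, resampling, and GeoTIFF input are out of scope by design.
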