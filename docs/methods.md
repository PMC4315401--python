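# Methods

`riversdm` chains four pieces of machinery: bioclimatic summarisation of
monthly climate, a presence-background maximum-entropy habitat model,
geometric post-processing (thresholding, polygonization, river overlay),
and line-transect density extrapolation. This note records the models,
their assumptions, the defaults and why, and what the synthetic
experiments do and do not demonstrate.

## Bioclimatic variables

The 19 standard layers are computed from 12 months of mean daily minimum
temperature, maximum temperature (°C) and precipitation totals (mm).
Monthly mean temperature is (tmin + tmax)/2. A "quarter" is any of the
12 circular windows of three consecutive months; warm/cold quarters are
chosen by window mean temperature, wet/dry quarters by window
precipitation sum, with ties broken by the earliest start month.
BIO2 is the mean over months of (tmax − tmin); BIO3 = 100·BIO2/BIO7;
BIO4 is 100 × the population SD of the 12 monthly means; BIO15 is the
precipitation CV with the conventional 1 + BIO12/12 denominator that
guards all-dry cells. Temperatures are kept as plain °C floats — the
×10 integer packing seen in some data releases is a storage artifact,
not part of the definition. A cell missing any month is nodata in every
derived layer.

## Grid conventions

Everything lives on a geographic (lon/lat, WGS84) grid: row 0 is the
northernmost row, values refer to cell centers, and a point maps to the
cell containing it under half-open intervals [west, east) × (south,
north]. A 1e-9-cell relative guard keeps points that sit on a cell edge
(up to float rounding) on the side those conventions dictate.
Continuous layers are aligned by bilinear interpolation between source
cell centers; categorical layers by majority vote of the covering source
cells (ties to the lowest code) with nearest-neighbour fallback when
upsampling. No reprojection is attempted — the source datasets this
mirrors are all distributed in geographic coordinates.

Occurrence records are cleaned by dropping flagged rows (e.g. migratory
stopover sightings), rows outside the grid or on nodata cells, and —
on by default, standard presence-background practice — thinning to one
presence per grid cell.

## The maximum-entropy model

The model estimates a Gibbs distribution over the background cells,
q(x) = exp(λ·f(x))/Z, maximizing the penalized presence log-likelihood

    L(λ) = λ·f̄ − ln Z(λ) − Σ_j β_j |λ_j|,

with f̄ the empirical feature mean over presences. Features are linear,
quadratic, pairwise-product, hinge and threshold expansions of the
continuous layers (plus indicators per categorical code), each min–max
scaled to [0, 1] on the background. Hinge and threshold knots sit at 50
equally spaced background quantiles per layer by default. Penalties
default to β_j = β_multiplier · s_j · c(class)/√m (s_j the feature's
background SD, m the presence count, c = 0.5 for hinge and 1.0
otherwise, β_multiplier = 1) — the same philosophy as the canonical
Maxent defaults without reproducing its empirical lookup tables, which
are not documented to reproducible precision anywhere we could verify.

The optimizer is scipy's L-BFGS-B on the split parametrisation
λ = u − v with u, v ≥ 0, which turns the L1 term into a linear one;
any convex solver is acceptable because the fit is certified after the
fact by the KKT conditions: Σ q = 1 and |f̄_j − E_q f_j| ≤ β_j for every
feature (binding, to tolerance, where λ_j ≠ 0). The test suite
additionally checks the penalized optimum against an iteratively refined
dense grid search on ≤4-feature, ≤30-cell instances (agreement within
1e-4).

The logistic output is p = q·e^H/(1 + q·e^H) with H the entropy of the
fitted q and implied prevalence τ = 0.5; it is a monotone transform of
q, so rankings (and AUC) are identical between raw and logistic output.
At prediction time q is renormalized over the prediction region for the
raw output, while the logistic output keeps the training Z and H so that
a uniform model yields p = 0.5 everywhere and predicting on the training
background reproduces the training distribution exactly. Feature values
outside the training range are clamped to [0, 1] after scaling and the
clamp count is logged.

Background defaults to 10,000 cells sampled uniformly without
replacement from the validity mask (presence cells remain eligible).

## Evaluation

Replicate evaluation splits presences 75/25 (background shared across
replicates, as in standard presence-background practice), fits per
replicate, and scores the rank-based AUC of presences against
background, ties counting ½. The cell-wise mean of the replicate
logistic maps — "the average model" — feeds the downstream habitat
steps. Jackknife importance refits with each variable alone and
withheld under one fixed, seeded split. Permutation importance shuffles
one raw layer across the combined presence + background evaluation
points and re-extracts features, so the measure reflects the variable
rather than any single feature; drops are floored at zero and
normalized to sum to 100%. Variables under 1% are pruned and the model
refitted. Response curves sweep one variable over its background range
with the others held at background means (categorical at the mode),
averaged across replicate models.

A note on two statistical subtleties the tests respect. First, the
training-vs-test AUC ordering: under strong L1 regularization on a
smooth landscape the gap is small (≈0.003–0.01 here), so resolving its
sign needs ~20 replicates, not 5. Second, partial-response optimum
recovery: with the default penalty the relaxed mean-matching lets the
optimizer prefer a flatter curve; the one-grid-step recovery of a known
optimum is demonstrated under a light penalty (β_multiplier 0.05) with
linear + quadratic features, while the default hinge-rich model is
checked to peak within 1 °C of the truth.

## Habitat mask and river overlay

The reclassification threshold is the mean predicted probability at the
presence cells of the averaged map (an alternative map-wide-mean
reading is available as an option), and "above the threshold" is
inclusive (p ≥ t) so the threshold-defining average case is suitable.
Suitable cells form 4-connected regions (diagonal adjacency must not
merge separate river corridors) traced as polygons with holes whose
vertices lie on cell edges; polygonize → rasterize at cell centers is
an exact round trip.

River overlay: lines below the Strahler order cutoff (default 6 — the
study species avoids small rivers) are dropped; the rest are intersected
with the habitat polygons planarly in lon/lat — the same approximation a
desktop GIS overlay makes, and negligible at ~1 km cells in
mid-latitudes — and the retained pieces are measured as great-circle
(haversine) lengths on a sphere of radius 6371.0088 km. Lines lying
exactly on a polygon edge count as inside, consistent with the
inclusive threshold.

## Population estimation

Each surveyed section contributes a density D = count/length
(birds·km⁻¹). Two estimators are always reported:

* unweighted-mean (default): N_c = mean(D)·L with spread SD(D)·L —
  each section is one observation of river-level density;
* length-weighted-pooled: N_c = (Σ counts / Σ lengths)·L with a Poisson
  standard-error spread — the pooled encounter rate.

On the packaged eight-section survey with L = 6,984 km these give
3,551 ± 498 and 3,543 ± 228 birds. The original study prints
3,561 ± 478; its exact averaging is not documented (neither the sample
nor the population SD reproduces ±478 exactly), so both bracketing
estimators are exposed rather than reverse-engineering the printed
number. Densities are presented rounded half-up to 2 decimals; all
propagation uses unrounded values.

## Synthetic data and what the experiments show

The generator emulates the statistical structure of the real inputs on
a 100×100 grid of 0.01° cells (seconds-scale tests with genuine spatial
structure):

* climate: a latitudinal temperature gradient (21 °C in the south,
  −8 °C per degree northward), a seasonal sinusoid of amplitude 10 °C,
  an 8 °C diurnal range, a west–east precipitation gradient (840–1,560
  mm annually) with a summer-peaking sinusoid, plus a smooth Gaussian
  random field (unit-SD white noise under a σ = 5-cell Gaussian blur);
* truth: logistic suitability with a Gaussian ridge at 17 °C annual
  mean temperature and 1,200 mm annual precipitation, widths 1 °C and
  80 mm. The widths were fixed from the closed-form AUC ceiling of the
  truth itself (presences ∝ p*, uniform background): broad widths cap
  any model's test AUC near 0.77, whereas these give a ceiling of ~0.94
  — a genuinely strong niche occupying a few percent of the landscape,
  matching the narrow winter band the real species occupies;
* rivers: 400 headwater sources descending an elevation surface (tilted
  plane + smooth noise) by steepest descent, merging into a dendritic
  tree with Strahler orders computed from the topology (orders reach
  ~3–4). The density matters: with sparse networks the clipped suitable
  length is dominated by whether a few reaches graze the patch edge; at
  400 sources river coverage is dense enough that clipped length tracks
  patch area;
* surveys: whole reaches of at least 5 km, counts Poisson(D_true ×
  length) with D_true = 0.5 birds·km⁻¹ — inside the 0.4–0.61 range
  observed in the field.

The end-to-end recovery experiment (five landscapes × five replicate
fits, 200 occurrence draws, 2,000 background cells) checks that mean
test AUC exceeds 0.9, that the averaged suitability map rank-correlates
with the generating truth above ρ = 0.8 (observed ≈ 0.97), and that the
interval N̂ ± 2·spread covers D_true × L_true in at least 90% of 50
simulated surveys. "True suitable habitat" is the generating
suitability thresholded by the study's own presence-mean rule — the
like-for-like definition of L_true. This experiment overlays the whole
synthetic network (order cutoff 1) because synthetic orders only reach
~4; the order filter is exercised separately by its own tests.

What passing does **not** show: the generator has no spatial sampling
bias (a road-proximity-style bias field is available but off by
default, so estimator tests are unconfounded), no detection failure in
surveys, independent climate gradients rather than the collinear
predictor suites of real climatologies, and no georeferencing error in
occurrences. Real-data results — AUCs near 0.97, a 0.55 threshold, and
thousands of suitable kilometres — require the external climate,
land-cover and hydrography rasters and are out of the package's scope.

## Numerical choices and degenerate inputs

Optimizer tolerances: L-BFGS-B ftol 1e-14 / gtol 1e-10, KKT certificate
enforced at max(10·tol, 1e-4) with tol = 1e-5 by default; weights below
1e-12 are snapped to zero. Constant layers contribute no features (a
warning is issued); a stack where pruning would remove every variable
aborts rather than fitting an empty model. Quarter ties take the
earliest window; categorical resampling ties take the lowest code.
Empty habitat masks polygonize to an empty set (not an error); an empty
river network yields L = 0. Single-replicate evaluations report their
SDs as absent, not zero. All generators and the pipeline are
deterministic functions of (parameters, master seed); reruns are
bit-identical.

## I/O formats

Rasters are read and written as ESRI ASCII grids (plain text,
`bio_1.asc` … `bio_19.asc` naming); rivers and habitat polygons as
GeoJSON; occurrences, survey tables and all reports as CSV; model
internals as a JSON document plus a plain-text per-feature "lambdas"
export; pipeline configuration as YAML, with the resolved copy written
beside every run's outputs.
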