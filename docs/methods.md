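# Methods

This note records the models, parameter choices and known limits of the
pipeline: what each stage assumes, what the synthetic landscape does and
does not emulate, and where genuinely open design decisions were settled.

## Raster model and IO

All layers travel as north-up single-band grids with square cells in a
projected metric CRS; cell (r, c) has its center at
(origin_x + (c+0.5)·s, origin_y − (r+0.5)·s) for cell size s. Geographic
(degree) rasters are rejected because every distance, area and kernel in the
pipeline is metric. GeoTIFFs are written through `tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA);
vectors are GeoJSON handled with `shapely`. Aggregation to the 1-km analysis
grid is block-wise (mean for continuous layers, circular mean for aspect,
majority for classes); trailing partial blocks use whatever cells exist, so
scene sizes need not be multiples of the aggregation factor. Slope/aspect
use Horn's 3×3 differences; aspect is the downslope azimuth clockwise from
north and is undefined (nodata) on flat cells.

Landscape diversity is windowed Shannon entropy over land-cover class
proportions; fragmentation is the fraction of rook-adjacent cell pairs
within the window whose classes differ (0 for homogeneous, 1 for a
checkerboard). Both are computed on a ~200-m majority land-cover product
with a 5-cell window — a deliberate echo of coarse global land-cover
layers — and then averaged to 1 km. The edge-density definition was chosen
because the named GIS heritage of these metrics does not pin a formula; both
are invariant to class relabeling, which the tests enforce.

## SAR preprocessing

Digital numbers calibrate as σ⁰ = 10·log₁₀(DN²) + CF, CF = −83 dB; DN = 0 is
nodata, negative DN an error. The Lee filter uses the local-statistics gain
k = max(0, 1 − c_u²/c_I²) with c_u = 1/√looks (looks = 4). Because speckle
is multiplicative on *linear power*, dB grids are converted to power,
filtered, and converted back; filtering directly in dB would see relative
variances of a fraction of a percent and flatten real texture away.

RFDI is computed on linear power by default — a ratio of logarithms has no
physical reading — with a dB option retained purely for sensitivity checks.
RFDI falls as HV rises at fixed HH, so degraded (volume-scattering-poor)
canopies score high.

## Texture engine

The GLCM of each 5×5 window accumulates co-occurrence counts of 32-level
min–max-quantized values over four distance-1 offsets, symmetrized and
normalized. Defaults (levels, window, offsets, symmetry) follow common
practice in SAR texture work and are all configurable. Eight Haralick
features plus first-order windowed mean/variance are emitted per band.
Two implementations exist: a numba kernel that visits only the touched GLCM
entries per window, and a plain per-cell python path; they are required to
agree to ~1e-10 relative (summation order differs) and the python path
doubles as the brute-force oracle in tests, alongside a cross-check of the
single-window GLCM against scikit-image. Border cells with incomplete
windows are nodata.

## Field plots and biomass models

Plot AGB is Σ exp(c₀ + c₁ ln D + c₂ (ln D)² + c₃ (ln D)³) kg over the
census (D in cm, all stems ≥ 30 cm), divided by 1000 and the plot area
(0.25 ha). The default coefficients (−2.134, 2.530, 0, 0) are a moist-forest
DBH-only form; they are configurable, and the scene generator inverts the
same coefficients so plot recovery is exact when plot noise is zero.

Predictor screening removes, while any pair of predictors correlates at
|r| ≥ 0.75, the member of the worst pair with the larger mean absolute
correlation to the rest (lexicographic tie-break) — a deterministic variant
of the usual caret-style filter. Plot predictors are the mean of each
texture grid over the 0.25-ha plot footprint (a 2×2 block of 25-m cells),
the standard plot-to-pixel matching rule.

The log-log model ln(AGB) = a + b·ln(x) is OLS with the half-variance
back-transform correction exp(s²/2) (switchable off). The random-forest
model uses 500 trees, tunes `max_features` over {p/3, √p, p/2} by pooled
10-fold out-of-fold correlation, and reports pooled r/RMSE/MAE/%bias with
%bias = 100·Σ(pred − obs)/Σobs. Importance is out-of-bag permutation
importance (mean OOB MSE increase per permuted feature across trees),
clipped at zero and rescaled so the best predictor scores 100.

Map fusion: the local prediction is aggregated to the 1-km global grid;
per cell, the Pearson correlation between local and global maps is computed
over 4×4, 8×8 and 16×16 windows; negative correlations are clamped to zero
(an anti-correlated local map earns no trust) and zero-variance windows
contribute zero weight; the mean clamped correlation w gives
fused = w·local + (1−w)·global. The convex-combination reading keeps every
fused value inside the per-cell envelope of its inputs, which is tested.

## Richness

Presence–absence: a species occupies a 1-km cell when its range polygon
overlaps the closed cell rectangle by more than `min_cover` of the cell area
(default 0: any positive-area overlap; edge touching never counts).
Stratified richness sums the columns passing a metadata filter; IUCN-listed
means CR ∪ EN ∪ VU ∪ NT. Richness is monotone under adding species and
additive over complementary strata, both enforced by tests against
cell-by-cell polygon intersection oracles.

## Driver analysis

The 1-km predictor stack holds fused AGB, altitude, slope, aspect
(circular-mean aggregated), road and river distance (exact vector distance
from cell centers), RFDI, the two landscape metrics and three bioclim
surfaces. The sample is a seeded uniform draw without replacement over
complete cells (1500 by default; fewer triggers a warning and uses all).
The SVR is a radial-kernel ε-SVR on standardized predictors, tuned over a
small C/γ grid by seeded 10-fold cross-validation. Importance per predictor
is max(0, 1 − SSE_smoother/SSE_null) from a lowess smoother (span 0.75,
interpolation delta 1% of the predictor range for speed) of richness on
that predictor alone, rescaled so the top predictor scores 100; a constant
predictor scores 0. Partial dependence clamps one predictor across its
observed range and averages predictions over all sampled rows, computed on
a 300-tree random-forest surrogate refit to the sample by default (any
estimator with a `predict` can be passed instead, including the SVR).
Signed effects are classical Pearson correlations; the spatially corrected
test lives with the congruence statistics.

## Congruence statistics

Gi* uses binary weights from a fixed 3-km distance band including the cell
itself (~29 neighbors on the 1-km grid) — a data-independent default since
GIS defaults vary; queen contiguity is available. The z-score follows the
standard formula with the global mean and population SD over data cells;
constant fields warn and return nodata. The vectorized evaluation (mask and
value convolutions) is tested cell-by-cell against a double-loop oracle at
1e-10, and its null rejection rate at |z| ≥ 1.96 calibrates to ~5% over 200
iid 30×30 fields. Hotspot classes at α = 0.05; AGB hotspots additionally
require AGB > 180 Mg ha⁻¹, a conventional high-biomass cutoff for Asian
tropical forests. No multiplicity correction is applied by default
(a Benjamini–Hochberg option would be easy to add but raw z thresholds are
the field convention for these maps).

Percent overlap of a class between two maps is reported under four
denominators (union of the class sets, either single set, whole study area)
because published overlap figures rarely state their convention; the union
is the default.

The corrected correlation reports the ordinary Pearson r; only the test
changes. Distance-class autocovariance matrices Σx, Σy (Sturges class count
on pairwise distances, capped at 30, equal-width bins; the diagonal holds
the variance) give Var(r) = tr(BΣxBΣy)/(tr(BΣx)·tr(BΣy)) with B the
centering matrix, floored at the independence value 1/(n−1), and the
effective sample size M = 1 + 1/Var(r) (hence effective df M − 2 ≤ n − 2).
For iid fields M ≈ n; heavily co-smoothed fields deflate M by an order of
magnitude or more. Grids beyond 2500 data cells are thinned by a seeded
subsample to bound the n² algebra.

## Synthetic landscape

The generator emulates a humid tropical mountain landscape: smoothed-noise
relief scaled to 0–1700 m; three land-cover classes carved by road
proximity plus a smooth disturbance field; latent AGB of 0–400 Mg ha⁻¹ from
class baselines (260/130/~2 Mg ha⁻¹) plus a smooth field (sd 45 Mg ha⁻¹,
correlation length 800 m) and a mild positive road-distance effect. The
radar link is σ⁰ = s_max − (s_max − s_min)·exp(−AGB/L) with L = 100 Mg ha⁻¹
(HV −22→−12 dB, HH −13→−7 dB), gamma speckle at 4 looks, and an extra
lognormal fine-scale term whose sigma grows from 0.04 to 0.59 across the
AGB range — the mechanism by which *texture* stays informative beyond
saturation, standing in for the real structural heterogeneity of tall
canopies. DN inverts the calibration exactly.

Field plots: 36 plots stratified half/half over the two forest classes;
the DBH census is drawn (truncated-exponential diameters ≥ 30 cm) until the
plot mass reaches target·(1 + 0.08·N(0,1)) and the last stem is sized by
inverting the allometry, so zero-noise plots recover local truth exactly.
The 8% plot noise represents allometric and co-location error.

The global AGB raster is truth aggregated to 1 km, smoothed (σ = 1 cell),
multiplied by 1.1 and perturbed by 30 Mg ha⁻¹ noise — a deliberately biased,
blurred oracle for fusion tests; setting bias/noise/smoothing to identity
values makes it exactly the block mean, which is tested.

Species ranges are built at 1 km: per species, suitability is a weighted sum
of standardized AGB, road distance, elevation and an aspect-preference
cosine plus noise (sd 0.5); cells above a species-specific quantile
(range size 15–50% of the scene) form the range polygon. AGB and road
weights are drawn positive around the configured effect sizes (defaults 1.0
and 0.8); elevation and aspect weights are weak (0.25/0.2) with random
signs, so they partially cancel across species. The drawn weights are stored
per species as recovery ground truth. Bioclim surfaces (rainfall,
temperature with a −6.5 °C km⁻¹ lapse, seasonality) never enter the habitat
rules and act as known-null predictors.

Determinism: every generator stage draws from `default_rng([seed, tag])`
with a fixed per-stage tag, so a (config, seed) pair reproduces the scene
bit-for-bit regardless of which stages are called.

What the generator does *not* emulate: topographic SAR distortion, optical
reflectance, cloud and atmosphere, range-map error relative to true
occupancy, or spatial sampling bias in plots. Passing tests therefore show
the *estimators* are correct and well calibrated under a known
data-generating process — not that any particular real landscape satisfies
that process.

## Problem sizes and experiment design

The default scene is 1240×1240 cells at 25 m (31×31 km, 961 one-km cells,
close to a typical sub-national study area) and runs the full pipeline in
about two minutes on one CPU. With only 961 complete 1-km cells the driver
sample warns and uses all cells; the driver-recovery experiments instead use
a 40×40 km scene on 100-m base cells (1600 one-km cells) so the full
1500-cell sample is honored while keeping all effect sizes and noise levels
at the defaults. Driver recovery is assessed over 20 seeds (AGB and road
distance must rank in the top 3 in at least 18), and the zero-effect null
over 20 seeds (all smoother R² below 0.05 in at least 19).

Two nulls deserve a note. The pure-noise check of the AGB model permutes the
plot responses against the real predictor table; at n = 36 the
cross-validated correlation of a single permutation is volatile, so the
check is on the median over seven permutation seeds. The no-association
null for hotspot overlap uses toroidal shifts (random rolls plus flips) of
the richness field rather than cell-wise shuffling: shuffling destroys the
field's autocorrelation and with it the large contiguous hotspots, making
any smooth field look significant; the shift null preserves the marginal
spatial structure and is the appropriate reference.

End-to-end determinism is verified by running a reduced configuration twice
and comparing the per-stage SHA-256 checksums of every artifact; the default
configuration is run once in full to confirm completion and plausibility of
its outputs.

## Known limitations

* The Gi* variance formula assumes the global moments are well estimated;
  very small grids (tens of cells) make the ±1.96 thresholds approximate.
* The effective-sample-size estimator is capped at n (equivalently Var(r)
  is floored at its independence value); negative estimated autocovariances
  cannot inflate the df.
* The fusion weight treats kernel correlation as the sole trust signal; a
  locally unbiased but uncorrelated map is down-weighted even if its mean
  is right.
* Lowess importance measures marginal association; two correlated drivers
  share credit, so ranks — not scores — are the meaningful output.
* The pipeline assumes a single projected CRS throughout; reprojection is
  out of scope.
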