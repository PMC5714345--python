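# ecoscape

Carbon–biodiversity congruence analysis for tropical forest landscapes,
rebuilt end to end over a synthetic study area with known ground truth.

Conservation planning for payment-for-ecosystem-services schemes (REDD+ and
kin) needs to know whether the places that store the most above-ground
biomass (AGB) are also the places that hold the most threatened and endemic
birds. Answering that requires a chain of methods that are usually scattered
across GIS packages and one-off scripts: radar calibration and texture-based
biomass regression, richness rasterization from range polygons, machine-
learning driver ranking, and hotspot-overlap statistics. `ecoscape`
implements that chain as one tested Python pipeline, and — because the field
plots, satellite scenes and range databases behind any real study are not
redistributable — pairs it with a synthetic-landscape generator so every
stage can be validated by parameter recovery.

It is written for remote-sensing ecologists and conservation data scientists
who want the statistical machinery with its assumptions exposed and tested.

## The methods at the core

* **SAR calibration** — ALOS-PALSAR-style digital numbers to backscatter:
  σ⁰ = 10·log₁₀(DN²) + CF with CF = −83 dB; Lee 3×3 speckle filtering on
  linear power; the radar forest degradation index
  RFDI = (HH − HV)/(HH + HV) on power, higher where canopies are sparser.
* **GLCM texture** — moving-window grey-level co-occurrence matrices
  (32 levels, 5×5 window, four distance-1 offsets, symmetric) yielding the
  eight Haralick statistics (mean, variance, homogeneity, contrast,
  dissimilarity, entropy, second moment, correlation) plus first-order
  windowed mean/variance. Texture keeps responding to biomass after mean
  backscatter saturates near 100 Mg ha⁻¹.
* **Biomass modelling** — 0.25-ha plots (all stems ≥ 30 cm DBH) converted by
  a DBH-only allometry; predictor screening at |r| ≥ 0.75; random-forest
  regression with 10-fold cross-validation reporting Pearson r, RMSE, MAE
  and %bias; out-of-bag permutation importance; and kernel-correlation
  fusion of the local prediction with a coarse global AGB raster
  (fused = w·local + (1−w)·global, w the clamped windowed correlation).
* **Richness** — presence–absence matrices from range polygons on a 1-km
  grid, summed within IUCN-listed (CR/EN/VU/NT) and endemic strata.
* **Driver ranking** — support-vector regression over ~1500 sampled 1-km
  cells; per-predictor importance as the R² of a univariate local smoother
  against the intercept-only null, rescaled to 100; partial-dependence
  curves; signed correlations.
* **Congruence** — Getis-Ord Gi* z-scores
  z_i = (Σ_j w_ij x_j − X̄ W_i) / (S·√((n C_i − W_i²)/(n−1)))
  over a fixed 3-km band including the cell itself; hot/coldspot classes at
  α = 0.05 (AGB hotspots additionally above 180 Mg ha⁻¹); percent area
  overlaps under four denominator conventions; and Pearson correlation with
  Dutilleul-corrected effective degrees of freedom estimated from the two
  fields' distance-class autocovariance.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic landscape (31 × 31 km at 25 m, 36 plots, 40 bird species):

```bash
cd analysis
python 01_generate_scene.py
python 04_fit_agb_model.py      # (02, 03 run calibration and texture)
python 07_congruence.py
```

prints, among other things:

```
cross-validated fit over 36 plots:
  r = 0.81, RMSE = 51.4 Mg/ha, MAE = 40.8 Mg/ha, %bias = 2.5
predicted AGB 81-350 Mg/ha; global map 38-440; fused 91-351
percent area overlap with AGB clusters (union denominator):
  iucn     hot-hot  77.4%   cold-cold  67.9%
  endemic  hot-hot  70.7%   cold-cold  64.7%
corrected correlations:
  AGB vs iucn     r = +0.78, effective df 25.3 of n = 961, p = 1.54e-06
```

Read: the texture model recovers plot biomass well out of sample (r = 0.81
against a plot-AGB spread of roughly 50–400 Mg ha⁻¹) with a small positive
bias; fusing with the biased global map narrows its range toward the locally
trusted values; and because this synthetic landscape was built with strong
AGB and road-distance effects on bird habitat, richness hot/coldspots
overlap AGB clusters far more than the weak overlaps typical of real
landscapes — the corrected correlation test still only grants ~25 effective
degrees of freedom out of 961 cells, since both fields are heavily spatially
autocorrelated.

The same pipeline is scriptable in one shot (`ecoscape run-all --out DIR
--seed 0`) or stage by stage (`ecoscape generate|calibrate|texturize|
fit-agb|richness|drivers|congruence`), with a YAML config, a JSON manifest
of per-stage checksums, and checksum-based resume.

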