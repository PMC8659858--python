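# Methods

`forestvol` estimates forest stand volume M (m³/ha) at field plots from
multi-source predictors and then sharpens the estimate with residual
ordinary kriging. Because the original field and flight data of this kind
of inventory campaign are rarely deposited, the package ships a synthetic
landscape generator with known ground truth; every stage is exercised and
tested against that truth.

## Plot volume

Individual stem volume uses the two-way volume equation

    V = a · D^b · H^c        (V m³, D cm, H m)

with the built-in coefficient rows for the three Northeast-China conifers
(*Larix olgensis*, *Pinus koraiensis*, *Pinus sylvestris* var. *mongolica*).
Plot volume is the sum of tree volumes divided by the plot area in
hectares, so M carries m³/ha. The equation is monotone in both arguments
and additive over trees; both properties are tested.

## Predictors (the 107-column candidate table)

* **Point-cloud metrics (61).** Heights are normalized by subtracting a
  TIN interpolation of the ground-classified returns (DEM fallback outside
  the hull), negatives clamped to 0. Metrics are computed over returns
  above a 2 m cutoff (conventional understory threshold; configurable —
  the column count does not depend on it): 15 percentiles
  {1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99} with linear
  interpolation, max/min/mean/median/std/var/mean-absolute-deviation,
  population skewness and non-excess kurtosis, canopy relief ratio
  (mean − min)/(max − min), coefficient of variation, and ten
  equal-height density fractions spanning [z_min, z_max] of the
  above-cutoff returns (top edge inclusive; a zero-spread cloud puts all
  mass in the bottom layer). The same statistic set minus relief ratio
  and densities is computed over intensities (25 columns).
* **Tree-top summaries (2).** A canopy height model (per-pixel max
  normalized height, 0.5 m pixels, empty pixels filled once by the 3×3
  median of populated neighbours) is searched for local maxima above the
  cutoff; H is the mean top height and W the mean diameter of the circle
  with each top's nearest-neighbour-assigned area. This local-maxima
  detector is a deterministic, reproducible stand-in for interactive
  watershed segmentation; the detected stem count N is returned by the
  API but deliberately kept out of the candidate table, which keeps the
  inventory at 107.
* **Visible vegetation indices (17).** NGRDI, EXG, CIVE, VEG (a = 0.67),
  EXGR, WI, VDVI, RGRI, NGBDI, GBRI, GBRVI, MGRVI, DEVI, GLI, COM, COM2,
  EXR, computed per pixel from the raw bands and the chromatic coordinates
  r, g, b and averaged over valid pixels. Formulas follow the published
  table verbatim — including EXGR = EXG − 1.4r − g, whose sign differs
  from the more common EXG − EXR form — so the combination indices COM and
  COM2 recompose exactly from their components. Pixels where a formula's
  denominator vanishes are masked per index.
* **Co-occurrence textures (24).** Each band is quantized to 64
  equal-width levels over its own min–max; every interior pixel's 3×3
  window contributes its four pixel pairs at offset (1, 1) (down-right),
  counted symmetrically, and eight statistics (mean, variance,
  homogeneity, contrast, heterogeneity = absolute-difference
  dissimilarity, entropy, second moment, correlation) are averaged over
  windows. Correlation of a zero-variance window is defined as 0; edge
  pixels without a complete window are excluded. 3 bands × 8 = 24.
* **Terrain and area (3).** Bilinear DEM altitude `h`, Horn's-method slope
  `slope` at the plot center, and plot `area` (ha).

## Screening and base learners

Predictors are screened by Pearson correlation against M: keep |r| ≥ 0.4
with two-sided t-test p < 0.05 (the screen is a significance filter, so
the "less than" direction is the default and the comparison is
configurable). No multiple-testing correction is applied, matching the
original protocol; the report flags this as a limitation.

Three base learners are configured at the study's hyperparameters and
delegated to scikit-learn: a 500-tree random forest (max depth 8, min
split 5, min leaf 2, ≤ 58 features per split — clamped with a warning when
fewer survive screening, bootstrap on), an RBF SVR (C = 150,
γ = 0.001), and a (50, 50) relu network trained with Adam (learning rate
0.01, ≤ 1000 epochs, early stopping with patience 20 on a 10% validation
split once at least 10 training rows are available). SVR and the network
standardize features *and the response* (z-scores, back-transformed at
prediction time): with the response left at m³/ha scale the ε-tube and C
of SVR are mismatched and Adam at learning rate 0.01 cannot reach the
required output bias within the epoch budget. The forest uses raw
features. All fits are deterministic given a seed.

## Residual geostatistics

The empirical semivariogram γ(h) = Σ(Z(xᵢ) − Z(xⱼ))²/2N(h) is binned into
12 equal-width lags up to half the maximum pairwise distance (defaults;
both configurable). Spherical and Gaussian models are fitted by weighted
least squares with weights N(h)/h², from a small grid of data-driven
starts, and the family with the lower weighted SSE wins. Conventions:
γ(0) = 0 exactly for both families (the nugget is a discontinuity for
h > 0 only), the spherical range is exact, and the Gaussian range is the
effective range at 95% of the sill (factor 3 in the exponent). The sill
effect nugget/(nugget + partial sill) indexes spatial structure.

Ordinary kriging solves the standard (n+1) system with the unbiasedness
constraint over a global neighbourhood (n ≈ 52 makes a search radius
pointless); γ(0) = 0 makes it an exact interpolator, which in turn makes
the hybrid prediction

    M(s) = M̂_base(s) + Ê_OK(s)

honor the observed value at every training plot. A fitted sill of zero
(e.g. perfectly fitted residuals) degenerates gracefully to the sample
mean of the residuals with equal weights. Near-pure-nugget fits are
flagged, since the range is then unidentified.

## Evaluation

Leave-one-out: for each held-out plot, screening, the base fit, its
training residuals and the residual variogram are all recomputed from the
remaining n−1 plots. Metrics are pooled over the n held-out predictions
(the per-fold averaging form is degenerate under leave-one-out because
each fold's R² denominator is zero; pooling is the standard convention and
leaves MAE unchanged). A per-fold variogram failure falls back to the
base prediction and is counted. Screening can optionally be done once
globally (`screen_in_fold=False`) to mimic the common, less conservative
practice. The improvement statistic is
(RMSE_base − RMSE_hybrid)/RMSE_base × 100.

## The synthetic landscape

The generator emulates the structure of the study system — ~52 square
plots of 0.06–0.2 ha in a 41/5/6 larch/korean-pine/scots-pine split,
elevations 170–575 m with slopes concentrated near 10–20°, ≥ 2.8 (default
3.0) returns/m² with ground/canopy classification and 0–255 intensities,
12 cm RGB tiles — on an 8 km synthetic domain:

* **Terrain** is a sum of six random harmonics (wavelengths 0.18–0.35 of
  the domain) rescaled into the elevation range, with the relief amplitude
  capped so no cell's Horn slope exceeds 28°.
* **Stands**: stem density uniform in 600–1200 /ha; DBH lognormal
  (σ_log = 0.3) around a site-dependent median (16 cm scaled by a terrain
  trend, default coefficients −0.4 elevation and −0.2 slope on normalized
  terrain, so part of the volume signal is explainable by the terrain
  predictors); heights follow a saturating Chapman-Richards-type curve of
  DBH with species-specific asymptotes (30/27/25 m) plus 1 m Gaussian
  noise; crown radii scale linearly with DBH. All stand knobs are
  recorded in the dataset manifest.
* **The planted residual field** is a zero-mean Gaussian random field
  sampled at plot centers by Cholesky factorization of the variogram
  covariance. The default truth model is spherical with nugget 600,
  partial sill 1800 and range 3.0 km — within the order of magnitude of
  published residual variograms for this method, with a sill effect of
  0.25 (clear structure) and a range well above the ~1.1 km mean plot
  spacing. The delivered response is tree-list volume + field (+ optional
  iid noise, default off), and the truth is stored separately so recovery
  is checkable.
* **Point clouds** are terrain-following: ground points sample the DEM
  plus 5 cm roughness; each tree contributes conical crown returns whose
  height is measured above the ground directly beneath the return (so
  normalized heights are bounded by tree height) plus one exact apex
  return. Intensity is drawn from separate ground (45 ± 8) and canopy
  (120 ± 20) distributions — arbitrary units, calibrated to nothing.
* **RGB tiles** paint green-dominant crown disks (with multiplicative
  per-tree brightness and radial shading, which preserve green dominance)
  over brown/grey mottled gaps, plus additive pixel noise (σ = 6) so the
  textures are non-degenerate.

What the generator does **not** emulate: photogrammetric geometry and
sensor physics, multiple returns and occlusion, species-specific crown
shapes and spectra, understory vegetation, co-registration error, and any
real radiometric calibration. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and the
recoverability of planted spatial structure — not real-data accuracy
levels, which depend on the original (undeposited) survey.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single CPU: the full feature stack runs on the 52-plot default landscape
once; variogram recovery uses 200-point fields over 20 replicates; and the
hybrid-direction experiment runs 20 replicate landscapes using the
stand-truth stage with tree-list stand attributes (mean DBH/height, stem
density, basal area, terrain, area) as predictors — the property under
test lives in the residual field and the kriging stage, not in the raster
feature stack, and this keeps 20 replicates to minutes. The experiment's
base learner is the SVR: its ε-insensitive fit does not interpolate the
training response, so its residuals carry the planted field essentially
undistorted, making it the cleanest (and fastest) probe of the
regression-kriging effect; the forest hybrid shows the same direction but
its bootstrap in-sample fit absorbs part of the field.

Degenerate inputs are defined rather than crashed: constant clouds give
zero spreads and relief ratio 0 with a warning, constant GLCM windows give
correlation 0, constant screening predictors are excluded, sub-minimum
clouds yield missing-value metric vectors. LAS I/O is a minimal
LAS 1.2 point-format-0 reader/writer (1 mm coordinate scale); rasters use
a plain .npy + JSON-sidecar dialect. Dataset manifests carry a SHA-256
checksum over the truth block so tampering is detected at read time.

## Known limitations

* The tree-top detector is intentionally simple; under closed canopies it
  undersegments, and W inherits the nearest-top area partition.
* The screening step inherits the original protocol's lack of a
  multiple-testing correction.
* Variogram fitting on ~50 residuals is noisy; per-fold fits in
  leave-one-out can degenerate to near-pure nugget, in which case the
  hybrid quietly adds (almost) nothing.
* Synthetic accuracy levels (R², RMSE) are not comparable to real-survey
  values and are not meant to be.
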