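# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of greenflux. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Raster model

A `Grid2D` is one single-band field on a regular geographic grid: origin at
the top-left pixel corner, row-major storage, rows running south, square
pixels in degrees (default 0.011305581°, ~1.25 km at mid-latitudes — this
metre figure is metadata only; all internal distances are planar degrees).
Pixel-center coordinates are used whenever cells become point locations
(kriging, point prediction). Nodata propagates: a nodata operand yields a
nodata output, and nodata pixels are excluded from every statistic.
GeoTIFF I/O goes through tifffile with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, a minimal WGS84 GeoKeyDirectory) and the
GDAL nodata convention; only single-band files and geographic coordinates
are supported — reprojection between CRSs is out of scope. Resampling is
nearest-neighbour for categorical grids (never inventing class codes) and
bilinear for continuous ones (exact on constant and affine surfaces); the
nearest/bilinear split is this package's convention, as is the per-month
variogram below.

## Synthetic-data generator

The generator emulates the statistical structure the analysis chain
assumes, with the generating truth stored alongside so that every stage is
testable against known ground truth.

* **Gaussian random fields** — white noise convolved with a Gaussian kernel
  (sd = `correlation_length` pixels) via FFT on a padded domain (no
  wrap-around), renormalized to unit variance in expectation. The field
  correlation function is exp(−h²/4L²), so the practical correlation range
  is ≈ 2L; tests of variogram recovery use that relation.
* **Climate** — each of the six drivers is base level + a southeast-high /
  northwest-low bilinear gradient + a seasonal cosine peaking in July + a
  persistent spatial pattern + independent monthly field noise, clipped to
  physical ranges (precipitation ≥ 0, RH ∈ [0, 100], etc.). Default levels
  and amplitudes (e.g. 2 °C base temperature with 10 °C seasonal amplitude,
  45 mm month⁻¹ base precipitation, 550 MJ m⁻² month⁻¹ radiation) are
  plausible magnitudes for a cold high-altitude plateau; they are fixed
  package defaults, not fitted values.
* **NDVI** — a logistic link: NDVI = lo + (hi−lo)·σ(η) with η linear in the
  standardized climate drivers plus a seasonal cosine, Gaussian noise
  (default sd 0.02), then clipped to [−0.2, 0.95]. The logistic keeps the
  link monotone in every driver and bounded, which is what the network
  recovery and correlation-sign tests rely on. Coefficients put most weight
  on temperature and precipitation.
* **Land use** — epoch 1 cuts a smooth Gaussian field by the class-share
  quantiles (giving spatially clumped classes); epoch 2 reassigns a seeded
  random cell subset (`change_rate`, default 2 %) following fixed
  transition preferences in which cropland converts mostly to forest and
  grassland, and grassland exchanges with barren land — producing the
  off-diagonal structure the transfer-matrix accounting needs.

Every generator is a pure function of (config, seed); reproducibility is
asserted bytewise in the tests. What the generator does **not** emulate:
orography, spatially varying seasonality, temporal autocorrelation beyond
the seasonal cycle, land-use-dependent NDVI, or any real-data error
structure. Passing recovery tests therefore show the chain is implemented
correctly and can extract known structure — not that it would achieve the
same skill on real plateau data.

## BP network

Single hidden sigmoid layer (default 10 units), linear output, full-batch
gradient descent with momentum (defaults: learning rate 0.2, momentum 0.9,
≤ 600 epochs, stop when the epoch-to-epoch MSE change falls below 1e−9).
These defaults were chosen so the synthetic NDVI task converges reliably;
with momentum the loss trace is not guaranteed monotone, so the
loss-descent test uses plain small-step descent. Weights initialize
uniformly in [−0.5, 0.5] from the seed. Inputs and target are min–max
normalized to [0, 1] on the training block; the bounds are stored in
`NetworkParams` and inverted on prediction, so callers always work on raw
scales. The train/validation split is by whole months (temporal block
split) to avoid leakage through the seasonal cycle. Month enters the
feature vector as a cyclic pair (cos, sin of 2π·month/12) by default; a
caller can disable this and fit per-month models instead.

Metrics follow the standard definitions: sample Pearson R; R² is the
square of R between predictions and observations (the linear-fit
convention), not 1 − SS_res/SS_tot; NRMSE is RMSE over the observed range
in percent. The Monte-Carlo robustness procedure perturbs each raw input
element by an independent multiplicative U(−ρ, ρ) factor (ρ = 0.02,
N = 300 by default), re-predicts, and reports the per-sample prediction
mean and sd plus the MSE distribution across simulations, where each
simulation's MSE is the mean of squared residuals against the observed
targets (the same quantity whose square root enters NRMSE). With ρ = 0 all
simulations coincide and the report reduces exactly to the unperturbed
MSE with zero spread.

## Kriging

Ordinary kriging with a spherical semivariogram; γ(0) = 0 with the nugget
as a 0⁺ discontinuity. The empirical semivariogram averages
0.5·(f(p_a)−f(p_b))² over pairs in equal-width lag bins (default 12 bins up
to the maximum pair distance; empty bins are flagged NaN). Fitting is
least squares weighted by √(pair count), with nugget and partial sill
bounded below by 0 and the range bounded by twice the largest lag; at
least three populated bins are required. Prediction solves one global
(m+1)×(m+1) system for all target pixels when m ≤ 500; above that, each
pixel uses its 64 nearest samples, grouping pixels that share a neighbour
set to reuse factorizations. Duplicate sample coordinates are rejected
(singular system) rather than averaged. Kriging is applied per month
independently — no spatiotemporal covariance — and each month fits its own
variogram.

## CASA

FPAR endpoints are fixed at [0.001, 0.95]. Per-class NDVI bounds default
to the 5th/95th percentiles of the pooled class NDVI (robust to
outliers); classes with fewer than 10 pixels fall back to global bounds
with a warning, and degenerate (constant) bounds are widened by a minimal
epsilon. SR bounds derive from the NDVI bounds through the SR formula.
The combined FPAR is the equal-weight mean of the NDVI- and SR-based
estimates — the standard CASA combination, adopted because a differencing
form can leave the stated FPAR range. NDVI is clamped at 0.98 before SR to
avoid the 1/(1−NDVI) singularity. The light-use efficiency ε defaults to
a constant maximum of 0.389 gC MJ⁻¹; an optional stress-product mode
multiplies it by a parabolic temperature response (peak 15 °C) and a
saturating moisture response, each clipped to (0, 1.2]. The constant
default is the honest minimal model: ε cancels in all relative and
structural results, and no stress formulation is imposed that the chain
cannot justify. Annual NPP is the pixelwise **sum** of the 12 monthly
maps (the annual unit gC m⁻² a⁻¹ implies a total, not a mean). Solar
radiation enters in MJ m⁻² month⁻¹; a converter from mean W m⁻² flux is
provided (fixed 365-day calendar).

## Carbon and land-use accounting

Wetland = the water land-use class by default (configurable), since no
delineation method beyond the class map is assumed. C = NPP × B with
B = 0.44 inside the mask, nodata outside; summaries cover masked pixels
only. The transfer matrix counts cells per (t₁ class, t₂ class) pair times
the cell area; row sums are t₁ totals, column sums t₂ totals, and the
grand total is conserved exactly. Percent changes and conversion
percentages use initial-epoch (t₁) class totals as denominators — the one
convention that reproduces every printed percentage of the packaged
reference table at 2-decimal rounding. A matrix read from a published CSV
may carry explicit marginal totals; these are authoritative for totals
(they absorb the print-rounding of body cells) and must agree with the
body within that rounding. Report output rounds half-up to 2 decimals;
internal computation is full precision. Per-class NPP summaries give the
class-mean annual NPP per year, its mean over years, and the OLS slope of
the class-mean series against calendar year.

## Correlations

Spearman rho is the Pearson correlation of mid-ranks (average ranks on
ties). Pairing defaults to pooled (pixel, year) records — annual
precipitation and radiation as sums, temperature and humidity as means,
against annual NPP — which maximizes sample size at desk scale; a
domain-mean monthly mode exists as an alternative. No significance testing
is performed.

## Pipeline

`run_pipeline` executes synth → train → point prediction (default 5 % of
pixels per month) → kriging → CASA → wetland carbon → transfer matrix →
correlations from one config. Every stochastic stage derives its sub-seed
deterministically from (global seed, stage name), so stage re-runs are
order-independent and one seed fixes the entire run. The manifest records
every output with a SHA-256 checksum, per-stage timings and the seed
record; `validate_run` re-checks file integrity, NPP nonnegativity and
transfer-matrix conservation on the files themselves.

## Problem sizes

Unit tests run on 16×16 grids with one synthetic year; the end-to-end
pipeline tests use 12×12. The network-recovery experiment runs at
128×128 pixels × 24 months (393,216 samples), the package's reference
condition for demonstrating skill recovery; the acceptance script uses the
same size for recovery and 64×64 × 2 years for the end-to-end run. These
sizes are the package's desk-scale defaults, chosen so the full suite runs
on a laptop.

## Known limitations

* Geographic degrees only; no projected CRS, no geodesic distances. At
  continental extents the planar-degree metric distorts the variogram.
* The BP trainer is plain batch gradient descent — no regularization,
  architecture search or early stopping on validation loss.
* Kriging ignores the nugget's measurement-error interpretation when
  predicting at sample sites (exactness holds only for nugget 0).
* The stress-product ε mode is a simple bounded heuristic, not a
  calibrated temperature/moisture limitation model.
* Real-data magnitudes (regional NPP means, wetland carbon ranges)
  depend on external forcing datasets and are outside what the synthetic
  generator can reproduce; the package demonstrates the chain's
  correctness, not those magnitudes.
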