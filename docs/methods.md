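# Methods

## The estimation model

`oxymap` estimates near-surface oxygen concentration (OC, % by volume) from
three drivers: elevation (m), air temperature (°C) and leaf area index (LAI,
dimensionless). The model has two deliberately simple stages.

**Stage 1 — composite index.** Each driver is Min–Max scaled to [0, 1] over
its observed range in the training points, then combined linearly:

    Tmp = w_E·N_E + w_T·N_T + w_L·N_L

The weights are *fixed relative contributions*, not fitted coefficients:
defaults −0.3958 (elevation), +0.3550 (temperature), +0.2492 (LAI), whose
absolute values sum to 1. Elevation suppresses OC (thinner air aloft);
temperature and vegetation raise it (thermal expansion of the column from
below, photosynthetic oxygen production). The package treats the weights as
injected constants (`ContributionWeights`); deriving them from a multi-factor
correlation/PCA analysis is outside its scope. The model assumes these
contributions are constant in space and time — its central, and strongest,
assumption.

**Stage 2 — linear regression with Monte-Carlo cross-validation.** OC is
regressed on Tmp, but the fitting protocol is designed for sparse, noisy,
route-clustered field data where a single OLS fit would be fragile:

1. For each candidate training-set size m, draw `n_reps` uniform
   without-replacement splits of the n points into m training and n−m test
   points.
2. Fit OLS on each training subset; compute RMSE on its held-out points.
3. Summarize each m by the across-split mean slope, mean intercept, mean
   RMSE and RMSE standard deviation.
4. Select the m with the smallest RMSE standard deviation (most robust), and
   report the averaged line at that m. Ties break toward smaller m, then
   smaller mean RMSE.

The averaged-coefficient line is nearly unbiased for the generating line
(each subsample OLS estimate is unbiased; averaging reduces variance), and
the RMSE-stability criterion avoids both tiny training sets (unstable fits)
and tiny test sets (unstable error estimates).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `w_E, w_T, w_L` | — | −0.3958, 0.3550, 0.2492 | plateau-wide relative contributions, held fixed |
| slope, intercept | %/index, % | 1.0283, 20.2509 | published plateau-wide line; used whenever no fit is run |
| `n_reps` | splits | 50,000 | reference protocol; the bundled analyses and tests use 2,000, at which the split-averaged coefficients are already stable to well below their standard errors |
| `m_values` | points | full sweep 3..n−2 if unset | pass an explicit subset (e.g. {10, 30, 76, 150, 300}) for routine use |
| reference OC `mu0` | % | 20.946 | conventional well-mixed dry-air value the t-tests compare against |
| nodata | — | −9999 | GeoTIFF sentinel; propagates through every per-cell operation |

## Numerical choices

- **Normalization clamping.** Raster cells outside the training Min–Max range
  are clamped into [0, 1] before entering the index (configurable,
  `clamp=False` extrapolates). Clamping keeps predictions inside the
  calibrated index range, at the cost of flattening gradients beyond the
  sampled driver ranges. Bounds provenance is a choice: bounds computed from
  training points may be reused on rasters, or recomputed from the raster
  stack itself.
- **Per-split OLS** uses the closed-form covariance/variance ratio, vectorized
  across splits; splits whose training x values are all equal are redrawn (cap
  100) before failing. RMSE is computed on the held-out set only; its
  **standard deviation uses the population formula** (divide by `n_reps` —
  indistinguishable from the sample formula at thousands of splits, but stated
  for bit-reproducibility).
- **Seeding.** All randomness flows through `numpy` Generators. Each m gets a
  substream keyed by (seed, m), so CV results are bit-identical across runs
  and independent of the order the m values are swept in.
- **Ensemble uncertainty** is the per-cell population standard deviation of
  predicted OC across the averaged models of the cross-validation
  configurations (one model per m by default). Predictions are sorted along
  the ensemble axis before the reduction so the map is exactly invariant to
  model ordering.
- **Degenerate t-test samples** (zero variance) short-circuit to t = 0, p = 1
  when the mean equals the reference value, ±∞ and p = 0 otherwise.
- **Difference maps are July − January.** Warmer, leafier July conditions give
  a non-negative difference; the map operation itself is a plain per-cell
  subtraction with nodata propagation, so the caller controls the convention
  through argument order.
- **Season rule** for stratified summaries: months 6–8 are summer, 11–2
  winter; records in other months are excluded from the two-season table. The
  winter year is the calendar year of the timestamp. Stratum standard
  deviations use the n−1 denominator, confidence intervals are t-based 95%
  intervals for the mean — conventional choices where the source tables leave
  the construction unstated.
- **Instrument-group inference.** When a table has no instrument-group column,
  the group is inferred from the record year (2017→A, 2018–2020→B, 2021→C,
  2022→D); an explicit column overrides. Calibration regresses target-group
  readings on source-group readings, so raw source readings substitute
  directly into the fitted equation; group B is the default target (largest
  sample). Calibration coefficients always come from session data — none are
  hard-coded.

## Raster I/O

Rasters are single-band float32 GeoTIFFs in geographic WGS-84, north-up,
pixel-is-area, NW-corner origin, nodata −9999, written and read through a
lightweight tag-level GeoTIFF layer (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL_NODATA) built on `tifffile`. Inputs must be
pre-co-registered — there is no reprojection or resampling engine; shape,
transform and CRS mismatches raise a co-registration error. Grid shape is
always derived from transform + extent, never hard-coded.

## What the synthetic generator emulates — and what it does not

The generator produces the three inputs the pipeline consumes, with the
statistical couplings the model assumes:

- **Points** (default n = 422, matching the harmonized 2018–2020 modeling
  sample): elevations uniform over 2000–5500 m; temperature from a standard
  −6.0 °C/km environmental lapse rate off a 25 °C sea-level baseline plus
  1.5 °C Gaussian scatter; LAI decreasing with elevation and increasing
  eastward, clipped non-negative; OC generated *from the model itself* —
  index built with the default weights over the sample's own Min–Max bounds,
  line with the published slope/intercept — plus Gaussian noise of sd 0.0952%
  (the held-out RMSE scale of the fitted model, so synthetic CV curves land on
  the realistic error scale).
- **Rasters**: co-registered stacks on the 73.50–104.67°E × 26.05–39.91°N
  bounding box with stylized west-high/east-low topography, seasonal variants
  (July warmer by construction and LAI scaled up relative to January, on the
  same seeded noise field so the ordering holds cell by cell), and a nodata
  margin.
- **Calibration sessions**: a latent true OC per point, each group reading it
  through its own linear response plus small noise; group B is the identity,
  the CY-12C group (A) visibly offset, the other TD400 groups near-identity —
  reproducing near-perfect same-model agreement (R² ≥ 0.999).

What it does **not** emulate: real plateau geography (basins, ranges, valley
networks), route-clustered rather than uniform sampling, spatially or
temporally varying contribution weights, non-Gaussian or heteroscedastic
measurement error, and any nonlinearity or interaction between drivers.
Passing tests therefore demonstrate that the pipeline recovers its own model
family under realistic noise — they do not validate the model's adequacy for
real plateau data, which rests on the field campaign's own validation.

## Problem sizes used in the bundled analyses

The test suite and example runs use n = 422 points, m sweeps of
{10, 30, 76, 150, 300} with 2,000 splits per m, raster stacks up to 50×50,
and 1,000-replicate coverage simulations — sizes at which every quantity the
package reports (averaged coefficients, RMSE curves, coverage rates) is
stable to well within the tolerances asserted, while the full protocol
(3..419 sweep, 50,000 splits) remains available through the same interfaces.

## Known limitations

- The two-stage model is linear throughout; interactions and nonlinear driver
  effects are out of scope by design.
- Fixed contribution weights are a modeling assumption, not an estimate the
  package can update from data.
- Min–Max scaling ties predictions to the training driver ranges; clamping
  saturates the index beyond them.
- The GeoTIFF layer reads north-up pixel-scale/tiepoint files only (no
  rotated transforms, tiling is whatever `tifffile` writes, no overviews, no
  reprojection).
- The RMSE-stability selection criterion is a heuristic: with few splits the
  argmin of the RMSE standard deviation is itself noisy, which is why the
  reference protocol uses very large `n_reps`.
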