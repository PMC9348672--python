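# Methods

`plumascape` builds tissue-isotope prediction surfaces ("isoscapes") for
feather hydrogen: given monthly climate grids, monthly precipitation-δ²H
grids and a georeferenced table of feather δ²H values (‰ VSMOW), it
produces an ensemble random-forest prediction surface with per-cell
uncertainty, together with the intermediate products a practitioner
needs to judge it — the isotope-window scan, the covariate-elimination
profile, permutation importances, partial-dependence curves and
observed-vs-predicted validation metrics.

## Model and procedure

**Transfer model.** Feather keratin fixes hydrogen from diet and
drinking water, which trace back to precipitation. The pipeline
therefore models feather δ²H as an unknown smooth function of (i) the
amount-weighted precipitation-δ²H composite over a window of consecutive
months and (ii) bioclimatic and static environmental covariates, and
approximates that function with a regression random forest.

**Amount-weighted compositing.** For a window `w` of consecutive
calendar months (wraparound allowed),

    δ_w = Σ_{m∈w} P_m δ_m / Σ_{m∈w} P_m ,

with monthly climatological precipitation `P_m` as weights. Cells with
zero window precipitation are nodata (there is no water to weight by).
The weights come from the same monthly precipitation climatology the
BIOCLIM stage uses, keeping the two stages internally consistent;
per-year weighting is a conceivable alternative but climatological
weighting matches how the gridded isotope products are distributed.

**Window scan.** For every candidate window (all 12 start months at the
requested lengths; default length 3, the year-quarter convention), the
composite is extracted at the sample sites and feather δ²H is regressed
on it by ordinary least squares. The winning window maximizes r²; ties
go to the earliest start month, then the shortest length. Windows with
identical month sets (every start at length 12) are evaluated once, and
the full-year composite fit is always reported as the baseline. In
tropical regions there is no freezing "growing season" to fall back on,
so the scan is the operational way to pick the months during which
precipitation hydrogen enters the food web feeding feather growth.

**BIOCLIM variables.** bio1–bio19 are computed from monthly
climatologies over an arbitrary year range. Quarters are all 12 windows
of three consecutive months with wraparound (Nov–Jan and Dec–Feb
included); ties between equally wet/dry/warm/cold quarters resolve to
the earliest quarter in January-start order; standard deviations are
population SDs (divide by 12); bio15 uses the `1 + bio12/12` guard in
the denominator; temperatures are °C and precipitation mm with no ×10
integer scaling. Cells with zero annual temperature range have
undefined isothermality: bio3 is nodata there and a warning counts
them. The test suite checks all 19 variables against an independent
brute-force quarter-enumeration oracle.

**Covariate elimination (RFE).** Backward selection scored by 10-fold
cross-validated RMSE. Inside each fold a forest on all covariates
ranks them by out-of-bag permutation importance, forests on each top-s
subset are scored on the held-out fold, and the subset size with the
lowest mean RMSE wins (ties to the smaller size). Recomputing the
ranking inside each fold avoids the selection bias of ranking once on
all data; the final variable set is then read off a full-data ranking.
Importance ties break by column order. One outer repetition is the
default; repeated CV is available. Inside RFE the forests use the
p/3 default for mtry (never below 2) rather than a nested out-of-bag
search, which would multiply the fit count by the candidate-set size.

**Forest and ensemble.** Regression random forests with 500 trees by
default. `mtry` is chosen by out-of-bag RMSE over candidates 2..p —
mtry = 1 is excluded because single-covariate splits overfit weak
spatial signals. Importance is %IncMSE: the percentage increase in
out-of-bag MSE when one covariate's column is shuffled, averaged over
five shuffles; a near-zero baseline (constant response) yields zero
importance by convention. Partial dependence sets the covariate to each
of 25 equally spaced values spanning its observed range in every
training row and averages the predictions. The spatial prediction
averages 20 forests that differ only in their seed, trained on the
identical 80 % training matrix (bootstrap-resampled members are an
option, off by default); the per-cell mean, SD (population) and CV
(SD/|mean|, nodata where the mean is zero) form the isoscape product.
Because forest predictions are averages of observed responses, the
surface never leaves the training response range — a property the tests
assert on every run.

**Validation.** An 80/20 random split (training size ⌈0.8 n⌉; 192
samples give 154/38 — a published partition of 156/36 from the same
total is not reproducible by any simple random rule and is documented
rather than imitated; outcome-stratified splitting is available as a
flag). The training set is scored by 10-fold cross-validation with
five repetitions, pooling exactly n × 5 out-of-fold pairs (156 training
samples give 780 pairs, hence a regression on 780 points with 778
residual df). Metrics: `mae` is the mean absolute residual; `mse_paper`
is the mean squared residual — the quantity some published isoscape
validations print under the label "MAE", whose square root is their
RMSE (231.21 → 15.21, 34.73 → 5.89) — and `rmse = sqrt(mse_paper)`.
Keeping both avoids propagating the mislabel while staying comparable
with published tables. Calibration diagnostics come from the OLS fit
observed = a + b·predicted with t-tests of b against 1 and a against 0.

## Synthetic world

The generator replaces WorldClim/CRU/waterisotopes downloads and the
museum feather set with a Brazil-sized 60 × 60 lon/lat grid whose
structure mirrors the real system qualitatively:

* temperature with a latitudinal gradient, altitude lapse and seasonal
  cycle, `tmax > tmin` everywhere by construction;
* precipitation from a smooth mean-annual-precipitation field spanning
  roughly 400–3000 mm (wetter to the west) times a sinusoidal wet
  season peaking in the austral summer;
* monthly precipitation δ²H with a linear east→west depletion (values
  highest near the northeastern coast), a spatially varying wet-season
  amount-effect depletion, a seasonally migrating longitudinal
  gradient, and smooth month-specific anomalies (SD 4 ‰). The last two
  terms matter: with a purely additive seasonal cycle all window
  composites are ≈ 0.99 correlated and no scan could distinguish
  windows, which would misrepresent the month-to-month spatial
  variability of the real gridded products;
* static solar-radiation, wind-speed, vapor-pressure and altitude
  layers.

Feather values follow `d2h_f = β₀ + β_δ δ²H_p(window) + Σ β_c cov_c +
site + ε` with every coefficient, the window, the per-locality shared
effects and per-sample noise recorded in a truth object. Sites are
uniform or clustered around museum-like capture hotspots (Gaussian
jitter around k centers), optionally with several samples at one exact
locality. All randomness flows from one seed through named
sub-generators, so each stage is independently re-runnable.

**The museum-like preset** (`paperlike_config`) uses 192 samples over
129 localities clustered around 12 hotspots, a locality-shared effect
of 15 ‰ and residual noise of 20 ‰. The noise is sized so the pooled
cross-validated r² lands in the weak regime (~0.25) reported for
tropical feather isoscapes; the preset illustrates that regime and is
not a numerical claim about Brazil. On this preset the random 20 %
holdout — scored against the 20-member ensemble mean, whose
between-model variance is 20× smaller than a single model's — looks
systematically better than the pooled CV, and clustered placement
inflates that optimism relative to independent sites. This reproduces,
qualitatively, the caution that a high holdout r² under museum-hotspot
sampling overstates transferability. Because a random split gives
holdout and CV sets the same expected composition, the per-seed gap is
noisy at n = 38; the tests therefore assert the pattern as a mean over
three seeds rather than one draw.

**The reference-collection stand-in** (`synthetic_reference_samples`)
rebuilds a table with the published marginal structure of the Brazilian
Thraupidae museum collection — 192 samples, 129 unique localities, 49
species, feather values spanning exactly −107.3 to +5.0 ‰ with an
east-west gradient — because the original record table is distributed
only as a supplementary PDF. Individual rows are synthetic; only the
margins are meaningful, and the descriptive-statistics stage is what
the tests exercise on it.

**What passing tests do and do not show.** The synthetic world is
additive, smooth and noise-homoscedastic; real feather data add species
and feather-type effects, measurement error (~±2 ‰), molt-timing
uncertainty and a precipitation-isotope product with its own model
error. Recovery rates measured here are upper bounds on what the same
pipeline could do on real data; the structural checks (metric
identities, BIOCLIM correctness, bookkeeping, ensemble invariants) are
exact regardless.

## Numerical choices and degenerate inputs

* Point extraction is nearest-cell (the cell containing the point), not
  bilinear — matching the extraction default of the raster tooling this
  workflow descends from, and kept fixed for reproducibility.
* Samples outside the grid extent are flagged, never silently dropped;
  samples hitting nodata in any covariate are dropped with their ids
  listed.
* GeoTIFF I/O writes float32 with the standard GeoTIFF tags
  (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL nodata), so
  round-trips are exact at float32 precision and files open in GDAL/QGIS.
* Zero-variance predictions make regression diagnostics undefined: the
  report is flagged `degenerate` instead of raising.
* Identical ensemble member seeds give bit-identical members; the SD
  surface is then zero up to the rounding of the mean (≤ 1e-12).
* Problem sizes in the test suite (60 × 60 grids, 50–600 samples,
  60–300 trees) are chosen so every stage's statistical behavior is
  measurable while the whole suite runs in minutes; the library
  defaults (500 trees, 20 members) remain the field-standard values.

## Known limitations

* No spatially blocked cross-validation; the optimism experiments are
  the diagnostic for spatial dependence, not the cure.
* No reprojection engine: all layers must arrive on one geographic
  grid; only polygon masking of outputs is provided.
* No quantile regression forests or residual kriging; the SD/CV grids
  quantify between-member method uncertainty only.
* The window scan is a simple-regression screen: when strong covariates
  confound the isotope signal, the best-fitting window is not an
  unbiased estimator of the physiologically true integration period —
  the recovery experiment therefore generates feathers from the window
  composite alone.
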