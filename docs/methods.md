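# Methods

`riverchl` implements a multi-scale analysis of river chlorophyll-a (chl-a)
observations: in situ sonde fluorescence (relative fluorescence units, RFU),
discrete laboratory samples (µg L⁻¹), and multiband satellite reflectance.
This note records the models, the parameter choices that matter, and the
places where the design was genuinely open.

## The three observation scales and their joins

Boat surveys produce ordered, geolocated fluorescence tracks (one reading
every 15 s). Laboratory samples are collected at fixed sites along the
channel. Satellite scenes provide six reflectance bands (b2, b3, b4, b5, b6,
b8a — blue through narrow NIR on a Sentinel-2-like sensor) on a common 20-m
grid with a water/cloud validity mask.

Two joins connect the scales:

* **field ↔ laboratory**: all track points within a 0.4-km straight-line
  buffer of a site are aggregated by their *median* RFU (min/max retained
  for range bars). The buffer boundary is inclusive (≤ 400 m): "within" is
  read inclusively, and the choice is visible in one boundary test.
  Samples with no in-buffer points are flagged, never dropped.
* **field ↔ satellite**: each track point takes the value of the single
  pixel containing it (no neighborhood averaging, to avoid overlapping
  pixel arrays between adjacent observations) from the one scene per
  product within ±3 calendar days of the survey. Latency is signed
  (image − survey); equidistant scenes tie-break toward the earlier image
  — the data motivating this design report only non-positive latencies, so
  the tie rule is a documented convention. Consecutive points falling in
  the same pixel are all retained; spatial cross-validation folds, not
  deduplication, handle the autocorrelation.

All geometry is planar, in metres, in a single local CRS. At the scale of a
single river reach a projected CRS is metre-true, buffer tests become exact,
and no geodesic library is needed. Raster I/O uses plain multi-page TIFF
(band planes plus a mask plane) with a JSON sidecar carrying the
geotransform `(x_origin, y_origin, cell_size)` and CRS label.

## Spectral indices

Sixteen published band-arithmetic indices form the fixed predictor suite
(MCI and NDCI families, band ratios, fluorescence line heights). The
registry order is stable and defines feature order everywhere, so
importance reports are reproducible. Two equations required documented
decisions:

* **NDCI (S11)**: the source table prints `(b5−b4)/(b5−b4)`, identically 1
  and useless as a predictor; the cited literature defines the normalized
  difference `(b5−b4)/(b5+b4)`, which is the default. A strict
  `ndci_as_printed` flag reproduces the literal constant for audit.
* **S23BDA (S13)**: printed with a trailing constant factor 8, suspicious
  (the sibling two-band form multiplies a band) but not degenerate; the
  literal form is default and a `s23bda_times_b8a` variant is opt-in.
* **S14 / S17** are implemented as the exact algebraic simplifications of
  their printed three-term forms (`b3−b2` and `b8a−b4`) so the identities
  hold bit-for-bit rather than to rounding.

Division by zero propagates non-finite values instead of clipping so
downstream filters see invalid pixels explicitly.

## Fluorescence–concentration regressions

Ordinary least squares with fluorescence (RFU) as response and laboratory
chl-a (µg L⁻¹) as predictor — slopes are then in RFU per µg L⁻¹; the
orientation is a documented convention and users can transpose. Fits are
produced pooled, per site, and per day; correlation strength is summarized
by adjusted r², with group means reported raw and with negative values
floored at zero. p-values are classical two-sided slope t-tests with no
multiplicity correction across group models. Groups with n < 3 or zero
predictor variance return unfitted results with reason codes and are
excluded from means but listed. A sensitivity mode re-runs the suite with
the single maximum-RFU row (or all rows above a threshold) excluded and
reports deltas.

## Forest study design

The response is RFU; the predictors are the 16 registry indices. For each
survey day, rows are split 75%/25% stratified by response deciles
(quantile bins auto-collapse for small days; bins under 4 rows pool into a
round-robin allocation). The same per-day 25% test set serves all three
model types, which is what makes their error metrics comparable:

* **individual** — trained on that day's 75%;
* **leave-one-day-out (LOO)** — trained on *all* rows of every other day,
  tested on the held day's 25% only;
* **pooled** — trained on the union of all days' 75% portions.

With 11 usable days and 3 products this yields 3 × (11 + 11 + 1) = 69 runs.
A single master seed expands deterministically (`numpy` SeedSequence) into
per-run seeds for splits, folds and forests.

Hyperparameters (tree count, depth, predictors per split) can be tuned by
grid search minimizing mean held-fold MAE over eight spatially clustered
folds (k-means on position), with ties broken toward fewer trees, then
shallower trees, then fewer split variables. Folds are recomputed on each
run's own training rows. The default grid — trees {100, 300, 500}, depth
{4, 8, unlimited}, split variables {4, 8, 16} — is a documented,
overridable choice; tuning is off by default (fixed 300 trees, unlimited
depth, 8 split variables) because per-run grid search over 27 × 8 fits
dominates runtime without changing any qualitative conclusion. Whether the
original analysis tuned once globally or per model is unknown; per-run
tuning is what the harness implements when enabled.

**EDM bias correction.** Test predictions are remapped by empirical
distribution matching: each raw prediction gets its plotting-position
quantile p = (rank − 0.5)/n (ties average), which is inverted through the
reference ECDF by linear interpolation between order statistics. The
reference is the run's *training-set* observations: using test-day
observations would leak the target distribution into LOO runs, defeating
their purpose of emulating unseen days. EDM is a monotone remap — it never
reorders predictions.

**Metrics.** MAE and bias (mean(pred − obs); positive = overestimation) in
RFU, computed on EDM-corrected predictions by default. Aggregation across
days takes |bias| before averaging so signs do not cancel. Products are
ranked within each day (1 = lowest MAE, average ranks on ties, so three
products always sum to 6) and ranks averaged over days. Variable importance
defaults to the forest's impurity decrease (permutation importance behind a
flag), converted to within-run ranks and summarized (median, IQR) across
the daily models.

## Scene mapping

A fitted run applies to every valid pixel of a scene: indices per cell,
forest prediction, optional EDM remap with the run's training reference;
masked cells are NaN. An optional one-cell inward erosion of the water mask
suppresses shoreline anomalies and is off by default. The variability
summary compares the mean of per-date SDs (typical within-day spatial
variability) with the pooled SD over all dates (ddof = 1 throughout); a
ratio above 1 indicates temporal variability dominating spatial.

## The synthetic river generator

Because the motivating field campaign cannot be re-collected at desk scale,
every stage is exercised against a seeded forward model that reproduces the
*structure* of such a study:

* **Geometry**: a gently sinuous channel rasterized on the common 20-m
  grid, 220 km long by default, ~500 m wide, with 10 sampling sites at
  equal channel-distance intervals. The default grid is a 24-row swath
  around the centerline rather than a full bounding box (a meandering
  220-km reach in a bounding box is overwhelmingly no-data).
* **Latent chl-a field**: log-Gaussian along channel distance — an exact
  Ornstein–Uhlenbeck path with 30-km correlation length and within-day log
  SD 0.25 — whose day-level log-mean (centre 3 µg L⁻¹) varies with SD 0.6.
  Day-to-day variability therefore dominates within-day spatial
  variability, the regime the analysis is designed to expose.
* **Fluorescence**: rfu = yield_day · chl(1 + ε) + background_day, with a
  day-specific yield (0.23 RFU per µg L⁻¹ centre, CV 0.8) and a
  day-specific additive optical background (0.2 RFU centre, CV 0.6)
  standing in for fDOM/turbidity matrix effects and quenching. The yield
  spread mirrors the ~5× range of per-day calibration slopes seen in the
  field; the background decouples day-level RFU from day-level
  concentration, which is what makes the pooled RFU↔chl-a regression weak
  while per-day regressions stay strong. Both terms vanish when their
  scales are set to zero, recovering the exact multiplicative model used
  in noiseless-limit tests.
* **Reflectance**: a red-edge response — b5 rises at 8×10⁻⁴ per µg L⁻¹
  while the other bands respond an order of magnitude more weakly — on
  typical water baselines; each product label (AR/SR/TOA) then applies its
  own per-day per-band affine perturbation (gain SD 0.03, offset SD
  5×10⁻⁴) plus per-cell sensor noise (SD 10⁻³). Products differ *only* in
  these draws: the design allows, but does not force, product differences.
* **Clouds**: contiguous elliptical patches masking an expected 10% of
  water cells; image latency per day is drawn as 0 in 8/11 of cases and
  −1/−2/−3 otherwise, matching the cadence of a 5-day-revisit sensor
  paired with same-day surveys.

What the generator does **not** emulate: radiative transfer, bidirectional
reflectance, adjacency effects near shorelines, tides/advection, taxonomy-
dependent fluorescence response, or real geography. Passing tests therefore
demonstrate that the *pipeline* recovers the qualitative contrasts it is
designed to measure (individual < pooled < LOO error; strong per-day vs
weak pooled calibration; temporal > spatial variability) when the data have
that structure — not that any particular river does.

## Numerical choices and degenerate inputs

* Quantile stratification falls back to a single bin when the response is
  constant; split targets use largest-remainder rounding so the global
  75/25 fraction is honored within ±2 rows.
* EDM interpolation clamps at the extreme order statistics.
* Regression groups with n < 3 or zero predictor variance are unfitted by
  reason code, not exceptions; a day clouded out of the satellite record is
  skipped with a log entry.
* LOO requires ≥ 2 days and is skipped with a warning otherwise.
* Sample SDs use ddof = 1 everywhere.
* Forests are scikit-learn `RandomForestRegressor` with `n_jobs=1` and
  integer seeds below 2³¹ derived from the master seed.

## Problem sizes used in checks

The test suite and the acceptance script scale problem size, never study
conditions: unit tests use 2–5 day studies on 30–40-km channels; the
error-ordering and variability replications use 10 seeds at the default
11-day design (full track density for the ordering check; 200 points/day
and a 40-km channel for the raster replication); the acceptance script runs
the full default 11-day, 3-product study with 100-tree forests. Forest
sizes in replicated checks (25–60 trees) are reduced from the 300-tree
default; the qualitative contrasts being checked are insensitive to forest
size well below that.

## Known limitations

* The synthetic scene places chl-a variation only along the channel axis
  (cross-channel structure enters only through noise), so spatial folds on
  synthetic tracks cluster mostly by channel distance.
* The field↔satellite matchup assumes one scene per product per day; true
  tile mosaics and partial-coverage overpasses are out of scope.
* RFU is never converted to µg L⁻¹; the package deliberately reports model
  skill in the fluorometer's native units.
* The buffer uses straight-line, not along-track, distance.
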