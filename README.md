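# riverchl

Multi-scale chlorophyll-a (chl-a) monitoring analysis for rivers: how well
do in situ sonde fluorescence, discrete laboratory samples, and multiband
satellite imagery agree — and how much does the *timing* of training data
matter when modeling a temporally dynamic river from space?

The package is written for aquatic remote-sensing and harmful-algal-bloom
monitoring work. It provides, as a tested library plus CLI:

* the standard suite of 16 published spectral chl-a indices (MCI/NDCI
  families, band ratios, fluorescence line heights) over Sentinel-2-like
  bands b2–b8a;
* matchup joins across scales: single-pixel extraction within a ±3-day
  latency window, and 0.4-km buffer-median aggregation of track
  fluorescence around laboratory sites;
* pooled / per-site / per-day OLS calibration of fluorescence (RFU) against
  laboratory chl-a (µg L⁻¹), summarized by adjusted r²;
* a three-way random-forest evaluation design — **individual-day**,
  **leave-one-day-out (LOO)**, and **pooled** models sharing identical
  per-day stratified 25% test sets — with spatially clustered CV folds for
  tuning and empirical-distribution-matching (EDM, i.e. quantile-mapping)
  bias correction;
* MAE/bias evaluation, within-day product ranking, variable-importance
  rank aggregation, whole-scene prediction rasters, and a spatial-vs-
  temporal variability summary;
* a seeded synthetic river generator reproducing the statistical structure
  such campaigns exhibit (day-to-day variability exceeding within-day
  spatial variability; day-varying fluorescence yield; day- and
  product-varying atmospheric gain/offset; cloud patches), so the entire
  pipeline is testable without any download.

The central comparison: for each survey day *d* with matchup rows split
75/25 into train/test,

* individual: fit on train(d), test on test(d);
* LOO: fit on all rows of every day except *d*, test on test(d);
* pooled: fit on ∪ train(d′), test on each test(d′).

Identical test sets make the three MAE estimates directly comparable; the
individual < pooled < LOO error ordering quantifies how much unseen-day
conditions cost a satellite model in a temporally dynamic river.

EDM remaps raw test predictions ŷ by p = (rank(ŷ) − ½)/n followed by linear
inversion of the training-observation ECDF at p — a monotone remap giving
predictions the training response distribution.

## Worked example

```python
from riverchl import StudyConfig, SimulationConfig, HyperParams, run_full_study

config = StudyConfig(
    simulation=SimulationConfig(
        n_days=4, n_track_points_per_day=150, channel_length_km=40.0,
        along_channel_corr_length_km=8.0, n_sites=6, seed=11),
    hyperparams=HyperParams(n_trees=50),
    seed=11)
report = run_full_study(config)

print(report["aggregate"][["model_type", "product_label", "mean_mae"]])
print("pooled adj r2:", round(report["relation_summary"]["pooled_adj_r2"], 3))
print("per-day mean adj r2:",
      round(report["relation_summary"]["day_mean_adj_r2"], 3))
print("variability ratio:",
      round(report["variability"]["temporal_spatial_ratio"], 2))
```

prints

```
   model_type product_label  mean_mae
0  individual            AR  0.111898
1  individual            SR  0.115625
2  individual           TOA  0.107437
3         loo            AR  0.442991
4         loo            SR  0.434294
5         loo           TOA  0.432859
6      pooled            AR  0.199547
7      pooled            SR  0.237515
8      pooled           TOA  0.245481
pooled adj r2: -0.045
per-day mean adj r2: 0.835
variability ratio: 2.67
```

Reading the output: individual-day models are most accurate (mean MAE
≈ 0.11 RFU across days), the pooled model pays a clear penalty
(≈ 0.2 RFU), and LOO models — which never see the test day — pay a large
one (≈ 0.44 RFU): temporal variability, not data volume, is the binding
constraint. The calibration suite shows the same story at the field–lab
scale: pooling the 24 sample pairs across days leaves essentially no
fluorescence–concentration relation (adjusted r² ≈ 0, day-varying yield
and background swamp it) while per-day regressions are strong (mean
adjusted r² ≈ 0.84). The mapped prediction rasters vary more across dates
than across space (pooled SD ≈ 2.7× the mean within-date SD). Choice of
satellite product barely moves any of these numbers, as expected when
products differ only by per-day affine perturbations.

The same pipeline runs stage by stage from the shell:

```
riverchl simulate --config config.yaml --out fixtures/
riverchl matchup  --fixtures fixtures/ --out matchups/
riverchl relate   --matchup matchups/matchup_lab.csv --out relation/
riverchl fit      --matchups matchups/ --out fit/
riverchl evaluate --runs fit/ --out tables/
riverchl map      --fixtures fixtures/ --runs fit/ --out maps/
riverchl run-all  --config config.yaml --out report/
```

Real data can be substituted anywhere by matching the fixture schemas
(track/sample CSVs, multi-page band+mask TIFFs with JSON geotransform
sidecars).

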