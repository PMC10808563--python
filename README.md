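# rainlag

Kriged daily precipitation surfaces and lagged-precipitation models for
*Aedes aegypti* trap surveillance in arid, urbanized landscapes.

## The problem

*Ae. aegypti*, the urban vector of dengue, Zika, chikungunya, and yellow
fever, is abundant in desert metropolitan areas where rainfall would seem
too scarce to sustain a container-breeding mosquito. Whether precipitation
actually limits adult activity and emergence — and how much of the
population is instead supported by anthropogenic water (irrigation, storm
drains, ornamental features) — can be asked quantitatively when daily
precipitation is known *at each trap location* rather than as a regional
average. `rainlag` implements that analysis as a reusable pipeline for
vector-surveillance programs with a weather-station network and a weekly
trap grid:

1. **Daily precipitation surfaces** — kriging with external drift (KED):
   the field mean at location *s* is `b0 + b1·elev(s)`, residual structure
   follows a semivariogram `γ(h)` fitted automatically each day over the
   spherical, exponential, Gaussian, and Matérn families (initial sill =
   mean of the max and median binned semivariance, initial range = 0.1 ×
   bounding-box diagonal, initial nugget = minimum semivariance). Values
   below the 0.01-in measurability threshold, including small negative
   kriging output, are set to zero.
2. **Lag realignment** — each trap event is joined to the interpolated
   precipitation at its own cell for days 1–20 before collection
   (`lag1..lag20`), plus 10- and 20-day cumulative sums; events are thinned
   to one per trap per calendar month so overlapping windows cannot
   manufacture 7-day autocorrelation.
3. **Screening** — an independent logistic slope per lag day for presence
   (≥1 female) and a correlation per lag day for counts.
4. **Model comparison** — L1-regularized (LASSO) logistic presence models
   and Poisson abundance models over four specifications (intercept-only,
   daily lags, daily+cum10, daily+cum20), split 75/25 by site, scored with
   AUC-ROC (presence) and count-scale RMSE (abundance); percentile
   bootstrap CIs for coefficients.
5. **Spatial autocorrelation** — Global Moran's *I* on per-trap female
   totals over an equal number (60) of sampled events per trap, with
   `E[I] = −1/(n−1)` and analytic or permutation inference.
6. **Anthropogenic-water bound** — the low-precipitation threshold: the
   widest initial plateau of the maximum trap count as a function of 20-day
   cumulative precipitation; the share of females trapped below it is the
   minimum fraction of the population that precipitation cannot account for.

A fully seeded synthetic generator (`rainlag.synthetic`) emulates the whole
study design — clustered stations, elevation-dependent zero-inflated
precipitation fields with a known variogram, a 1-trap-per-square-mile grid,
weekly collections, and hurdle-model counts driven by known daily-lag
coefficients — so every stage is testable against planted truth without any
data download. Deposited real inputs (station CSVs, trap-count CSVs) are
ingested through the same readers.

## Worked example

```bash
printf 'n_stations: 40\nn_days: 140\nn_traps: 500\n' > sim.yaml
rainlag simulate --config sim.yaml --seed 3 --out bundle/
rainlag krige --stations bundle/stations.csv --elevation bundle/elevation.csv \
              --out surfaces/
rainlag align --traps bundle/traps.csv --surfaces surfaces/ --out lagmatrix.csv
rainlag compare --lagmatrix lagmatrix.csv --outcome presence --seed 3 \
                --out comparison.json
```

The `compare` step prints, for the bundle above:

```
null           AUC-ROC = 0.500
daily          AUC-ROC = 0.583
daily+cum10    AUC-ROC = 0.581
daily+cum20    AUC-ROC = 0.581
```

Read: the intercept-only model is uninformative by construction (all test
scores tie, so the rank-based AUC is exactly 0.5); the generator plants its
signal in the daily lags (strong suppression 2 days before collection, a
positive peak at day 10), and every spec containing the daily lags recovers
the same discrimination on held-out sites — attenuated below the
truth-lag ceiling because the predictors here are *kriged* from 40
stations, not the true fields. The cumulative terms are linear
combinations of the lags, so adding them changes nothing beyond noise.
`rainlag screen` on the same matrix reports the planted day-2 suppression
as a logistic slope of −3.54 with Wald CI (−4.62, −2.46) — negative and
clearly excluding zero.

The full pipeline (`rainlag run --config pipeline.yaml`) writes each
stage's artifact plus a manifest with row counts, exclusion tallies, seeds,
and a config hash; identical configs give byte-identical JSON results.

## Layout

- `rainlag.datamodel` — typed records, CSV readers, surface I/O, cleaning
- `rainlag.geostat` — variograms, automatic fitting, KED kriging
- `rainlag.lags` — lag extraction, thinning, the analysis matrix
- `rainlag.screening` — per-lag univariate screens
- `rainlag.models` — LASSO suite, AUC/RMSE, site split, bootstrap
- `rainlag.spatial` — equal sampling, Global Moran's I
- `rainlag.summaries` — effort tables, monthly activity, threshold bound
- `rainlag.synthetic` — the seeded study-design generator
- `rainlag.pipeline`, `rainlag.cli` — orchestration and the `rainlag` command

See `docs/methods.md` for the statistical details and design choices.
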