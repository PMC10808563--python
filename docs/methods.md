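# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Precipitation units and cleaning

Precipitation is carried in inches end to end because both analysis
thresholds are defined in inches: 0.01 in is the measurability limit of
standard gauges, and 0.02 in (of 20-day cumulative precipitation) is the
scale on which the low-precipitation bound is reported.
`datamodel.inches_to_mm` is the single conversion helper. Interpolation can
produce small negative values and positive values far below measurability
(e.g. 1e-10 in); `clean_precip` maps everything below 0.01 in to exactly
zero. The rule is idempotent and applied at every surface boundary: after
kriging, and defensively on extracted lags.

## Planar projection

Station and trap coordinates are projected to a local planar system before
any distance computation: an equirectangular mapping about the bounding-box
center with the east–west scale fixed at the central parallel, which agrees
with a local transverse Mercator to first order. Over a county-scale box
(~100 km) the distance distortion is far below station spacing, and planar
distances keep the variogram and kriging algebra simple and exactly
testable against brute-force oracles.

## Variogram estimation and automatic fitting

The empirical semivariogram bins half squared differences by separation
distance, with right-closed bins up to a cutoff (default one third of the
maximum pair distance) and the mean pair distance as each bin's abscissa.
Fitting minimizes weighted squared residuals with weights `N_j / h_j²`
(pair count over squared distance), the common automatic-fitting default,
over four families. Initial values follow the automatic-fit convention:
sill₀ = (max + median)/2 of the binned semivariances, range₀ = 0.1 × the
bounding-box diagonal, nugget₀ = the minimum semivariance. The Matérn
smoothness is selected over {0.5, 1, 2} rather than optimized freely — the
weighted-SSE surface in ν is nearly flat and free optimization mostly
returns arbitrary values; note that ν = 0.5 reproduces the exponential
model exactly, so "exponential" and "Matérn(0.5)" are one model with two
labels. Families that fail to converge are skipped with a warning; the
minimum-SSE family wins.

A caveat established during development: with realistic noise, binned
semivariances do **not** identify the family label reliably — simulated
exponential fields are fitted as spherical or Matérn(1) in a large minority
of replicates because the candidate curves differ by less than the binning
noise. The tests therefore check that the *fitted curve* tracks the
generating curve (and that parameters are recovered to 1% from noiseless
curves), not that the label is recovered from noisy data.

## Kriging with external drift

The mean model is `b0 + b1·elevation`; the augmented semivariance system
is solved per target with the drift row appended to the ordinary-kriging
constraint. Implementation details that matter:

- The station-station matrix has a zero diagonal, and a target exactly at a
  station uses γ = 0 on the right-hand side, so predictions at stations
  honor the observation (exact interpolation; with nugget 0 this is also
  the theoretical property the tests assert at 1e-8).
- Weights sum to 1 (unbiasedness) via the constraint row; asserted at 1e-10.
- If every station reports the same elevation the drift column is collinear
  with the intercept and the system is exactly singular; the solver detects
  zero-variance drift and reduces to ordinary kriging.
- Duplicate station locations are averaged per day before solving.
- Neighborhood: global by default with a 64-nearest cap for dense days; the
  capped and global solutions agree when the cap covers all stations.
- Days on which all reporting stations share one value (all-dry days above
  all) short-circuit to a uniform surface: any predictor whose weights sum
  to one reproduces a constant field exactly, and the empirical variogram
  of a constant field is degenerate, so no system is solved. Days with
  fewer than 3 stations yield an all-missing surface with a warning.
- Negative predictions are removed by `clean_precip`, never by clamping
  inside the solver.
- The elevation grid is resampled to the analysis grid bilinearly.
- Precipitation is kriged untransformed; a transform hook is the natural
  extension point if skewness becomes a problem on real data.

## Lag realignment and thinning

Day *k* means the calendar date *k* days before collection; the collection
day itself is not a predictor. Extraction is point-in-cell on the daily
surface (no smoothing), with half-open cells so every location maps to one
cell. Thinning keeps, per trap and calendar month, the earliest-dated event
(ties broken by trap id, then input order), which is deterministic and
idempotent; calendar months — not rolling 30-day windows — define the
groups. cum10/cum20 are row sums of the lag vector, so `cum10 ≤ cum20`
always holds for cleaned (non-negative) lags.

## Screening

Presence: an intercept-plus-slope logistic fit per lag day, with Wald 95%
CIs; complete separation is flagged with an infinite-slope sentinel rather
than a crash. Abundance: Pearson correlation per lag day (Spearman by
flag), Fisher-z CIs, with an optional positive-count-only scope that
separates zeros from non-zero counts. In arid data a lag day can be dry at
every thinned event; its screen is then inestimable and flagged, not an
error.

## Model comparison

Specifications: intercept-only, the 20 daily lags, daily+cum10,
daily+cum20 (cumulative-only variants available). Sites are split 75/25 by
trap: traps are shuffled by seed and accumulated greedily, keeping or
dropping the final trap to land the realized observation share nearest the
target, so no trap contributes to both sets.

Presence models are L1 logistic fits on raw inches; the penalty is chosen
by 5-fold CV over a log-spaced path *including zero*, and the unpenalized
fit wins whenever the path fails to improve validation log-loss. Abundance
models are L1 Poisson GLMs on centered, unit-variance predictors (so
coefficients are comparable), with the penalty chosen by CV deviance;
predictions are mapped back to the count scale and scored by RMSE. AUC-ROC
is computed by midranks, which equals exhaustive pairwise concordance
including the half-credit tie convention — hence the intercept-only model
scores exactly 0.5 on any two-class test set, a useful built-in identity
check. Constant (all-dry) predictor columns are reported as eliminated with
coefficient 0; only a design with no varying predictor at all is an error.

Because cum10/cum20 are linear combinations of the daily lags, the
daily+cumulative specifications nest the daily one; on synthetic data their
held-out metrics differ only by noise, and no ordering among them is
asserted. The discriminating comparisons are daily vs the null and daily vs
the cumulative-*only* specs, where signal placement forces the ranking.

Bootstrap CIs are percentile 2.5/97.5 over case-resampled replicates
(rows by default, whole sites by flag), refitting at the penalty chosen
once on the full data; more than 10% failed replicates aborts with
diagnostics, and a single replicate yields a flagged degenerate CI.

## Spatial statistics

`equal_sample` keeps CO2 traps with at least 60 events and draws exactly 60
(seeded, without replacement) from traps with more, summing female counts
per trap. Moran's I uses inverse-distance weights with a zero diagonal and
no row standardization by default; the scheme is recorded in the result,
and row standardization is available (it is the convention of the `ape`
reference implementation against which a frozen cross-check test runs).
The analytic null uses the randomization (kurtosis-adjusted) variance;
a ≥999-draw permutation null is the alternative. `median_trap_spacing` is
the median nearest-neighbor distance over de-duplicated trap locations.

## Effort summaries and the low-precipitation threshold

`summarize_effort` groups by year and trap type and re-derives every
percentage from that row's integers, rounding half away from zero to one
decimal (presentation convention of surveillance tables); the totals row
sums the groups and counts unique traps across all of them.

The threshold scan computes M(t), the maximum female count among events
with cum20 ≤ t, over a candidate grid (default 0.01–0.50 in steps of
0.01 in, matching the reporting precision of the bound). The threshold t*
is the largest candidate up to which M stays within a 5% relative
tolerance of its initial value; M is a running maximum and hence
non-decreasing, so the plateau is well defined. Reported alongside t*:
the share of all events at or below it, the share of female-positive
events (the alternative denominator, logged because the two readings
differ), the share of all trapped females (the anthropogenic-water lower
bound), and M(t*). Exact plateau equality is available via tolerance 0.

## The synthetic generator

`SyntheticConfig` fixes everything: seed, station network, climate, trap
grid, and planted effects. Defaults encode an arid two-season study
region: wet-day probability 0.08 with a 0.25-in mean wet-day field gives
roughly 7–8 inches per year and leaves ~19% of 20-day windows completely
dry, so the low-precipitation analysis has mass to work with; the
variogram is exponential (sill 0.04 in², range 15 km); elevation adds
0.05 in/km; traps sit on a 1-mile grid with weekly collections at a
per-trap jittered weekday. Wet-day fields are Gaussian draws from the
configured variogram (dense Cholesky at stations ∪ trap locations),
shifted by the mean and elevation effect and truncated at zero — the
truncation doubles as natural within-wet-day zero inflation while
preserving spatial correlation where positive.

Counts follow a hurdle model: presence is Bernoulli on a logit carrying
the planted daily coefficients, and positive counts are 1 plus a negative
binomial (Poisson in the dispersion → ∞ limit) whose log mean carries the
abundance coefficients. This makes presence ≡ (count ≥ 1) hold exactly
while both planted coefficient vectors remain the generating truth. The
default planted pattern mirrors the biologically motivated shape the
analysis is meant to detect: strong suppression two days before
collection (−6 per inch), weaker suppression at day 8 (−2), a positive
peak at day 10 (+4), unit positive effects on most other days, and zero
on days 1, 5, 9, 13, 20.

What the generator does **not** emulate: seasonality (wet days are i.i.d.,
not clustered into monsoon and winter rains), temperature and humidity
drivers, trap-level heterogeneity beyond location, measurement error in
counts, and station outages. Passing recovery tests therefore show the
estimators work when the model class is correct and effects are
stationary; they do not certify performance under the confounding present
in real surveillance data.

Two statistical realities shaped the recovery tests. First, unit-magnitude
planted effects sit near z ≈ 2 at ~2,500 thinned events, where sign
recovery across seeds is necessarily well below 90%; the ≥90% bar is
applied to the strongly planted effects (days 2, 8, 10), which recover at
100%. Second, with i.i.d. dry days a specific lag day is occasionally dry
at every thinned event, making that coefficient inestimable for that seed;
screens flag it and models eliminate it.

## Problem sizes

Recovery suites run at ~2,500 thinned events (500 traps, 140 days, 40
stations) over 10 seeds; kriging tests use 12×12 grids with 15–100
stations; the end-to-end pipeline test uses 25 stations, 45 days, and 40
traps. These sizes put every Monte-Carlo margin well away from its
threshold while keeping the full suite in minutes on one CPU.

## Known limitations

- The variogram family label is not identifiable from noisy binned
  semivariances (see above); downstream kriging depends only on the curve.
- L1 nonzero counts along a penalty path are monotone on the instances
  tested, but monotonicity is not a theorem for LASSO paths in general.
- The Poisson abundance model ignores overdispersion; the generator's NB
  dispersion knob exists precisely to study that misspecification.
- The anthropogenic-water fraction is a lower bound: it counts only females
  trapped after precipitation-free windows, not any broader dependence of
  the population on human water sources.
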