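# Methods

This note documents the models, numerical choices and known limitations of
`reefbleach`, in the order the pipeline runs.

## Climatologies

Monthly means are arithmetic means of available days; a month with under
50% day coverage is flagged missing rather than averaged from a thin
sample. Two satellite-style products can be merged by per-calendar-month
bias correction on their overlap (corrected = coarse + [clim_fine(m) −
clim_coarse(m)]), applied after the coarse product has been brought to the
fine grid.

**MMM.** The maximum-monthly-mean baseline follows the Coral Reef Watch
recentering convention: each of the 12 climatological monthly means is
shifted by `−slope · (T_full − T_heritage)` before taking the maximum,
where the temporal midpoints are means of month midpoints — 2000.5 for
1985–2015 and 1988.786 for the heritage years {1985–1990, 1993}. The
per-cell trend `slope` (°C/yr) is fitted on the monthly series **with
calendar-month fixed effects** (x and y demeaned within each calendar
month before pooled least squares). A naive fit on the raw monthly series
aliases the seasonal cycle into the slope — on a trend-free periodic
series over few years the raw-series slope is catastrophically wrong
(≈0.34 °C/yr in a 3-year test) — whereas the fixed-effects fit returns
exactly 0 there and recovers a planted trend exactly.

**MMM_max** averages each year's warmest monthly mean over complete years
(all 12 months present) and is never below MMM, because a maximum of
means cannot exceed a mean of maxima. **sigma_m** is the sample SD
(n−1) of the annual maximum monthly SST; at least two complete years are
required.

**Interpolation.** Inverse-distance weighting uses great-circle distances
(k = 12 nearest finite sources, power 2, exact at coincident points);
bilinear interpolation is the standard 4-node blend, missing outside the
source hull (coastal gaps are then filled by IDW). Both are bounded by the
source value range.

## Thermal indices

HotSpots are positive-only anomalies above the baseline (MMM or MMM_max).
DHW accumulates the **full** HotSpot value over the trailing 84 days
whenever `HS_i >= threshold` (not the excess above the threshold), divided
by 7 to express °C-weeks; DHM is the analogous 12-month sum in °C-months;
DCW accumulates non-negative (MMM − SST) over 84 days with the filter
fixed at 0. Windows are trailing and end on the observation date. Filter
comparisons are `>=`; alert comparisons are strict `>` (monthly SST > 30,
weekly SST > 31.5 °C, DHW > 4, DHM > 1, and the variability-scaled rule
DHW > 2.45·sigma_m, 2.45 °C⁻¹ being the reciprocal of the global median
sigma_m). Up to 10% of a window may be missing, in which case the sum is
renormalized by (window / valid days); gappier windows are rejected.

## Observations and quality control

Records are validated on parse (coordinate ranges, severity vocabulary,
severity/flag consistency, study-era dates) with per-line rejection
reasons. Records flagged as small non-thermal bleaching events
(microatolls, disease, predation) are reclassified to nonbleaching when
the local DHW is exactly zero; the operation never promotes a record to
bleached and is idempotent. Spatial autocorrelation of model residuals is
checked with Moran's I under row-standardized inverse great-circle-
distance weights (configurable cutoff; an explicit weight matrix may be
supplied) with a two-sided permutation p-value (999 seeded permutations)
rather than the normal approximation.

## Models

The GLM is a maximum-likelihood binomial-logit fit; perfect separation is
detected (saturated fitted probabilities or optimizer failure) and
flagged rather than silently reported. The random forest follows the
regression-on-binary convention — 500 regression trees on the 0/1
response, p/3 candidate predictors per split, seeded — so the ensemble
mean is a probability. Variable importance: for the GLM, Akaike-weight
sums over the all-subsets model space (2^p fits); for the forest,
permutation importance (chosen over node-purity importance, which is
biased toward high-cardinality predictors); both rescaled so the top
variable reads 100%. Overdispersion is residual deviance per residual
degree of freedom, passing below 1.5.

## Threshold and variable optimization

Predicted positive means probability ≥ threshold. The evaluation
threshold is chosen from the unique predicted probabilities by TPR–TNR
sum maximization; among maximizers the smallest candidate wins
(mathematical ties are snapped at 1e-10 because equal TPR+TNR sums can
differ in the last float bit).

Skill is estimated by repeated random 70/30 splits (10 repeats). The
evaluation threshold is optimized on the **training** predictions and
applied unchanged to the test set, preventing leakage; a compatibility
switch allows test-side optimization. Split draws depend only on the
seed, repeat count and table length, so every candidate in a search is
scored on identical splits — candidate contrasts are paired and not
masked by split noise. Summaries are means ± SE over repeats.

The filtering-threshold grids are generated by integer steps (i/100) to
avoid floating-point drift: 151 `alpha` candidates on [0.00, 1.50] and
241 `beta` candidates on [0.10, 2.50]. The combination search evaluates
the 15 non-empty subsets of the four optional covariates (historical
variability, turbidity, depth, current speed) on top of the always-
included thermal index, DCW and UV-B; the empty subset is additionally
computed and logged (`in_search = False`) for transparency but never
selected. Joint searches evaluate the full repeats × combinations × grid
factorial (22,650 alpha-mode or 36,150 beta-mode model fits). Selection
is the strict argmax of mean test TSS, so the reported best configuration
dominates every row of its search trace by construction.

## Prediction and the screening scenario

Grid predictions average the 10 cross-validation models cell by cell; the
binary alert map cuts the ensemble-mean probability at the mean of the
per-repeat optimized evaluation thresholds (per-member voting is
available by flag). The warmest month of a year is the calendar month
with the highest domain monthly mean SST in that year. Bleaching
frequency is the percentage of evaluated years in alert. The screening
scenario multiplies UV-B by 0.6 and turbidity by 1.4 (shading by fishery
nets reduces UV and raises apparent turbidity by about 40%); for any
model with a positive UV-B effect and negative turbidity effect this can
only lower predicted probabilities.

## Synthetic data: what it emulates and what it does not

The generator provides every input the pipeline needs with known ground
truth. Daily SST is `mean + A(x)·cos(2π(doy − peak)/365) + trend·t +
interannual summer anomaly + heat waves + N(0, noise_sd)`; day-of-year is
leap-adjusted so each calendar date repeats its seasonal value exactly,
making degenerate scenarios (no noise, no trend) give bit-identical
annual maxima and hence sigma_m = 0. Defaults describe a subtropical
reef domain: 25 °C mean, 4 °C seasonal swing peaking mid-August
(day 227), 0.02 °C/yr warming, 0.3 °C daily noise, 0.2 °C interannual SD
of the summer peak, cohort size 668, observation dates July–October.
Covariate fields are smooth positive surfaces (UV-B ≈ 5 W m⁻² with a
summer-peaked monthly cycle, K490 ≈ 0.05 m⁻¹, currents ≈ 0.2 m s⁻¹ per
component, depths 1–15 m). Typhoon tracks are kinematic stand-ins (south
origin, northward drift, constant wind) sufficient for the calm-duration
index. Observations are Bernoulli draws from a logistic model with
explicit coefficients. One global seed feeds independent per-generator
substreams, so adding a generator never perturbs another's draws.

Two planted worlds exist for structure-recovery experiments. The
**planted-filter world** gives each record an 84-day HotSpot window whose
signal days sit just above the planted filtering threshold and whose
outcome-independent nuisance days sit just below it with high
cross-record count variance; under-filtering floods the predictor with
noise, over-filtering discards signal, so the test-TSS profile of a
threshold search peaks at the planted value by construction (10-seed mean
recovery 0.53 for a planted 0.50). The **planted-support table** draws
covariates on realistic scales with a response using only the thermal
index, DCW, UV-B and turbidity; variability, depth and current speed are
pure noise. The strict-argmax selection reliably includes the influential
turbidity covariate but cannot reliably exclude noise covariates: with
paired 10-repeat splits the mean test-TSS cost of one spurious GLM
parameter is ≈0.004 against selection noise of ≈0.011 (n = 668), so
exact-support selection is a near-lottery among the turbidity-containing
subsets. A one-SE parsimony rule would fix this but would break the
trace-dominance guarantee of the selection rule; dominance was kept.

What the generator does **not** emulate: ocean dynamics, advection,
cloud-driven gaps, observer biases, spatially correlated noise, species
composition, or typhoon physics. Passing tests therefore demonstrate the
statistical machinery — index arithmetic, threshold optimization,
recovery of known structure — not predictive skill on real reefs.

## Problem sizes

Default test and acceptance runs use small grids (3×3 to 6×6 cells at
0.01°), 1985–2016 daily spans, cohorts of 200–668 records, 10-repeat CV,
and full 151/241-point threshold grids (with instant stub models for the
count identities, and single-covariate GLMs for the planted-threshold
searches). These sizes keep a complete run in minutes while exercising
every code path at the study's statistical scale.

## Known limitations

* GeoTIFF export is not provided; all grids are NetCDF (scipy backend,
  NetCDF3).
* The sigma-scaled alert compares DHW (°C-weeks) against 2.45·sigma_m
  numerically, as the alert rule is conventionally stated; the units do
  not formally cancel.
* GLM all-subsets importance is exponential in the candidate count
  (fine for p ≤ 7).
* The typhoon calm index treats each track point as exposing a disc of
  configurable radius (default 100 km) for one reporting interval
  (default 6 h); no wind-field model is attempted.
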