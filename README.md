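# reefbleach

High-resolution coral-bleaching risk modelling: thermal-stress indices of
the degree-heating-week family, statistically optimized thresholds,
GLM/random-forest bleaching models evaluated by the true skill statistic,
and spatial prediction including a UV-screening management scenario.

## The problem

Reef-building corals bleach when sea-surface temperature (SST) stays above
the local historical summer maximum. The operational warning index is the
**degree heating week**,

    DHW = (1/7) * sum over the trailing 84 days of HS_i,  where HS_i >= alpha,
    HS_i = max(SST_i - MMM, 0),

with `MMM` the warmest of the 12 climatological monthly mean SSTs and a
filtering threshold conventionally fixed at `alpha = 1 °C` (alert at
DHW > 4 °C-weeks). That convention misses bleaching driven by sub-degree
stress, ignores local SST variability, and says nothing about co-stressors
such as UV-B radiation, water turbidity (K490), cooling spells (degree
cooling weeks, DCW), depth or currents.

This package implements the full statistical refinement pipeline for
presence/absence bleaching records:

* **Climatologies** — monthly aggregation, inter-product bias correction,
  trend-recentered MMM, `MMM_max` (mean of each year's warmest month,
  always ≥ MMM), historical variability `sigma_m` (SD of annual maximum
  monthly SST), IDW/bilinear downscaling.
* **Indices** — HotSpots, DHW/DHM/DCW with configurable filtering
  thresholds (`alpha`, or `beta * sigma_m` scaled to local variability),
  trailing weekly/monthly SST, standard alert rules.
* **Models** — binomial-logit GLM and random-forest regression on the 0/1
  response; Akaike-weight and permutation variable importance;
  overdispersion check.
* **Optimization** — evaluation metrics ACC/TPR/TNR and
  `TSS = TPR + TNR − 1`; evaluation-threshold choice by TPR–TNR sum
  maximization; repeated 70/30 cross-validation; filtering-threshold grid
  search (151 `alpha` candidates on [0, 1.5], 241 `beta` candidates on
  [0.1, 2.5], 0.01 precision) and the 15-subset covariate-combination
  search with DCW and UV-B always retained.
* **Prediction** — ensemble-mean probability maps, multi-year bleaching
  frequency (% of years in alert), and a screening scenario (UV-B × 0.6,
  turbidity × 1.4, emulating fishnet shading).
* **Synthetic data** — a first-class generator (gridded SST with seasonal
  cycle, warming trend, interannual variability and heat waves; smooth
  covariate fields; typhoon tracks; Bernoulli observations from a known
  logistic model) so every stage is testable without satellite downloads.

## Worked example

```python
import numpy as np, pandas as pd
from reefbleach import (SyntheticScenario, generate_sst, monthly_aggregate,
                        build_climatology, hotspots, degree_heating_week,
                        ModelSpec, repeated_split_cv)
from reefbleach.models import logistic

scenario = SyntheticScenario(grid_shape=(4, 4), years=(1985, 2016), seed=42)
sst = generate_sst(scenario)
clim = build_climatology(monthly_aggregate(sst))
print(f"MMM at first cell:      {float(clim.mmm[0, 0]):.2f} degC")
print(f"MMM_max at first cell:  {float(clim.mmm_max[0, 0]):.2f} degC")
print(f"sigma_m at first cell:  {float(clim.sigma_m[0, 0]):.2f} degC")

hs = hotspots(sst.values[:, 0, 0], float(clim.mmm[0, 0]))
dhw = degree_heating_week(hs[: sst.indexes['time'].searchsorted('2016-09-01')], 0.5)
print(f"DHW on 2016-08-31:      {dhw:.2f} degC-weeks")

rng = np.random.default_rng(42)
table = pd.DataFrame({"dhw": rng.uniform(0, 8, 668)})
table["bleached"] = (rng.uniform(size=668)
                     < logistic(-2.5 + 0.9 * table["dhw"])).astype(int)
cv = repeated_split_cv(table, ModelSpec(family="glm", variables=("dhw",)), seed=42)
s = cv.summary()
print(f"CV mean TSS:            {s['tss_mean']:.2f} +/- {s['tss_se']:.2f} (SE)")
print(f"Evaluation threshold:   {s['threshold_mean']:.3f} +/- {s['threshold_se']:.3f}")
print("Fitted model:          ", cv.models[0].formula())
```

prints

```
MMM at first cell:      29.04 degC
MMM_max at first cell:  29.28 degC
sigma_m at first cell:  0.21 degC
DHW on 2016-08-31:      4.37 degC-weeks
CV mean TSS:            0.62 +/- 0.01 (SE)
Evaluation threshold:   0.553 +/- 0.015
Fitted model:           logistic(-2.48 + 0.853*dhw)
```

Reading the output: `MMM_max` exceeds `MMM` because the warmest calendar
month shifts between years; the 2016 summer accumulated 4.37 °C-weeks of
filtered stress at this cell (above the conventional 4 °C-weeks alert); on
the synthetic cohort the cross-validated true skill statistic is 0.62,
with the probability cutoff that balances sensitivity and specificity at
about 0.55 rather than the naive 0.5; and the refitted logistic slope
0.853 recovers the generating value 0.9 within sampling error.

A full pipeline run (synthesis → climatology → QC → collinearity screen →
cross-validated models → probability/frequency maps → screening scenario)
is one call:

```bash
reefbleach run-all config.yaml --out run/
```

Every run writes a `manifest.json` with the seed, the resolved
configuration, and SHA-256 hashes of all artifacts.

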