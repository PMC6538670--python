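# seditherm

Cumulative-impact analysis of suspended sediments and thermal stress on
corals: from raw water-quality sensor series and fortnightly colony health
scores to a Monte-Carlo classification of synergistic versus antagonistic
cumulative effects and the spatial footprint of dredging impact.

## Who this is for

Researchers and environmental analysts working with coral monitoring data
collected along a dredging (or other turbidity) pressure gradient: 10-minute
logger series of turbidity (NTU), benthic PAR, temperature and a relative
sedimentation index per site, plus repeat photo-surveys of tagged colonies
scored on a 7-category scale for partial mortality, bleaching and sediment
cover. Because such monitoring datasets are usually access-restricted, the
package ships a first-class synthetic-data generator with known ground truth
that emulates the full design (~17 sites at 0.19–32.8 km from the pressure
source, ~530 days, fortnightly surveys, ~10 branching and ~23 massive
colonies per site), so every stage of the pipeline is testable end to end.

## The model

Expected fortnightly coral loss is a two-branch hurdle pathway:

```
E[loss] = P(bleach) · P(mort | bleached)   · E[loss | mort, bleached]
        + (1 − P(bleach)) · P(mort | unbl.) · E[loss | mort, unbleached]
```

* **Bleaching** — site-level binomial GAMM of bleaching-event counts vs a
  light × temperature surface (cubic regression splines, basis dimension
  k = 5; site random intercept). Bleaching is a gated phenomenon: it occurs
  only above ~29 °C daily-mean temperature *and* above ~4 mol photons
  m⁻² d⁻¹.
* **Incidence** — colony-level binary GAMM of partial-mortality events
  (a colony's mortality score increasing between consecutive surveys) vs
  light, temperature, sedimentation (massive corals) and bleached status;
  colony random intercept.
* **Loss** — beta regression of the midpoint-scale tissue loss, fitted only
  where an event occurred (the hurdle), with bleached status and starting
  live cover; colony random intercept.

Candidate predictor sets are compared by full-subsets AICc (≤ 3 predictors,
|Pearson r| < 0.4 collinearity screen, null model included), with variable
importance as summed Akaike weights; an a-priori path analysis decomposes
total standardized effects per pressure pathway (SSC → light/sedimentation →
mortality; temperature → bleaching → mortality).

Fitted sub-models are composed by Monte-Carlo draws into three scenarios
across a descending light grid *L*: thermal-alone (31 °C, 8.8 mol photons
m⁻² d⁻¹), dredging-alone (25 °C, grid), and cumulative (31 °C, grid). The
theoretical additive curve is thermal-alone + dredging-alone; cumulative
minus additive is the interaction index (positive = synergistic, negative =
antagonistic), from which two light thresholds are derived, and predicted
loss vs log distance to dredging yields the 50% effect distance (ED50).

## Worked example

Run the full pipeline under the default study-condition configuration
(17 sites, 530 days, fortnightly surveys, 1000 Monte-Carlo draws; ~40 s on
one CPU):

```python
from seditherm import pipeline

cfg = pipeline.RunConfig(outdir="scratch/readme_run2")
pipeline.run(cfg)

import json
th = json.load(open("scratch/readme_run2/thresholds.json"))
ed = json.load(open("scratch/readme_run2/effect_distance.json"))
b = th["branching"]
print("branching peak antagonism light:", b["l_peak_antagonism"], "mol photons m-2 d-1")
print("branching crossover light:", round(b["l_crossover"], 2))
print("branching ED50 at 31 degC:", round(ed["branching"]["T31"]["ed_km"], 2), "km")
print("massive ED50 at 31 degC:", round(ed["massive"]["T31"]["ed_km"], 2), "km")
```

prints

```
branching peak antagonism light: 2.8 mol photons m-2 d-1
branching crossover light: 0.36
branching ED50 at 31 degC: 0.33 km
massive ED50 at 31 degC: 1.41 km
```

Reading the numbers: for branching corals the probability of an
*antagonistic* cumulative effect peaks at moderate shading (2.8 mol photons
m⁻² d⁻¹) — turbidity-driven light reduction suppresses bleaching, so the
combined impact is *less* than the sum of the isolated impacts. Below 0.36
mol photons m⁻² d⁻¹ the median interaction turns positive: severe low-light
stress outweighs the shading benefit and the cumulative impact becomes
*synergistic*. Under high thermal stress, predicted loss falls to the
midpoint between its nearest-site maximum and farthest-site minimum within
a few hundred metres to ~1.4 km of the dredging. The run directory also
contains the per-light scenario curves, AICc comparison tables, path-analysis
totals, decay curves, a structured log and a SHA-256 manifest; rerunning the
same config reproduces the manifest exactly.

The same stages are available from the shell:

```bash
seditherm simulate --out demo --days 120 --sites 6 --seed 1
seditherm score-events --panel demo/colony_panel.csv --out demo/events
seditherm run --out demo/full
```

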