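# Methods

This note documents the models, numerical choices and limitations of the
package in one place. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pressure metrics from raw sensor series

Turbidity screening removes negative NTU readings and isolated spikes: an
interior value is removed iff it exceeds 3 NTU *and* 2.5× the mean of its
two neighbours. The rule is applied in a single pass against the *original*
neighbour values (no iteration to a fixpoint), which makes it deterministic
and idempotent; endpoints, having only one neighbour, are subject only to
the negativity rule. If a neighbour is missing the spike test is skipped for
that value.

The daily light integral (DLI, mol photons m⁻² d⁻¹) is the time integral of
10-minute PAR over the civil day: trapezoidal between samples plus a
rectangular closure from the first sample back to 00:00 and from the last
sample to 24:00, so a constant 100 µmol m⁻² s⁻¹ day integrates to exactly
8.64. Days with under 80% of the expected 144 readings are flagged missing;
the 14-day trailing running mean requires at least 50% of its window. Both
completeness thresholds are package choices, recorded in output metadata.

Per survey interval (survey *t* → *t+1*, days in `(t, t+1]`): "worst case"
light is the interval **minimum** of the 14-day running-mean DLI, worst-case
sedimentation the **maximum** sedimentation index, worst-case temperature the
**maximum of daily-mean** temperature, and the SSC proxy the mean screened
NTU. The qualitative term "worst case" admits other operationalizations;
both `temp_worst` and `temp_mean` are exposed and the model-input choice is
a configuration switch (default `temp_worst`, consistent with bleaching
being gated on daily-mean temperature exceedance).

## Colony scores and events

Categories 1–7 map to percentage bands 0 / 1–5 / 6–33 / 34–65 / 66–95 /
96–99 / 100 with midpoints 0, 0.03, 0.19, 0.495, 0.805, 0.970, 1. The
generator's inverse binning places `round(100p)` in the band whose upper
edge is inclusive. A partial-mortality event is a mortality-score increase
between consecutive surveys; its loss is the midpoint difference, so
per-colony losses telescope to `midpoint(final) − midpoint(first)`.
Mortality scores are validated to be non-decreasing (scores are cumulative
mortality; the dead fraction of a colony cannot shrink). Bleached status
latches from the first bleaching evidence onward by default — thermal
history plausibly matters for subsequent mortality — with a concurrent-only
option. Intervals touching an excluded survey (e.g. dislodged colonies) are
dropped. Sediment-cover adjudication (tissue under sediment scored live
until revealed dead) is assumed applied upstream by the scorer, since
photographs are not package inputs.

## Mixed-model engine

The three response sub-models are binomial or beta GLMMs. No Python package
in the environment provides binomial/beta mixed models with a *marginal*
log-likelihood (needed for AICc comparison), so the engine is authored
here:

* a single random-intercept factor is integrated out by Gauss–Hermite
  quadrature (13 nodes by default) — effectively exact at these group
  counts, giving an AICc-valid marginal likelihood;
* crossed random intercepts (site × fortnight in the distance model, where
  no AICc is needed) use a joint Laplace approximation with an inner Newton
  solve for the random-effect modes.

Optimization is L-BFGS-B with analytic gradients (quadrature path) and
variance parameters bounded in a safe range (log SD ∈ [−10, 5], log beta
precision ∈ [−5, 12]). Unstable fits (|coefficient| > 15, the signature of
complete separation, e.g. all-zero bleaching counts) are automatically
refitted with a ridge penalty on non-intercept coefficients and flagged.
Parameter uncertainty is a multivariate-normal approximation around the
MLE, with covariance from the numerical Hessian of the marginal
log-likelihood; non-positive-definite Hessians (possible numerical artefacts
of the approximated objectives) are eigenvalue-clipped with a warning. An
MCMC backend would be a drop-in alternative — the Monte-Carlo pathway only
consumes draws — but the normal approximation keeps desk-scale runs in
seconds.

Smooths are natural cubic regression splines with k = 5 knots at training
quantiles (four free columns after centring), built from
`scipy.interpolate.CubicSpline` on knot indicator vectors, with linear
extrapolation beyond the boundary knots. The basis dimension is deliberately
small so fitted partial effects stay near-monotone and interpretable;
smoothness is controlled by fixed df rather than penalized selection (the
fixed-df fallback), which is logged by construction. The
light × temperature bleaching surface uses a tensor product of two k = 3
marginal bases by default (a product-ramp option exists). Factor-by-smooth
interactions (e.g. a light effect differing by bleached status) multiply
factor dummies into the spline columns.

The beta family clips losses into [1e-4, 1 − 1e-4]; a loss of exactly 1
(whole-colony death in one interval) has zero beta density, so the upper
clip is required. Quasi-binomial would be the alternative mean-variance
contract; beta was chosen for a proper likelihood (hence AICc).

Temporal autocorrelation is not modelled: only one water-quality summary per
survey interval enters the models, and colony/site random intercepts absorb
the dominant non-independence.

## Full-subsets comparison and path analysis

All predictor subsets of size ≤ 3 are enumerated, excluding any model with
two continuous predictors at |Pearson r| ≥ 0.4 (computed on the model input
rows after missing-data removal); the null model (intercept + random
effects) is always included. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), weights
ω = exp(−Δ/2)/Σexp(−Δ/2), importance = Σω over models containing the
variable (models where it appears only inside an interaction count).
Interactions consume their constituents' predictor slots only. The "best"
model is the AICc minimum, or with the parsimony rule the model with fewest
terms within 2 AICc units of it (ties: fewer parameters, then lexicographic).

Path analysis operates on site × survey means: predictors averaged over the
interval, response the logit of mean proportional mortality clipped to
[1e-4, 1−1e-4], all columns standardized to zero mean and unit sample SD.
Each node with parents is regressed on its parents by OLS; for a recursive
DAG with uncorrelated errors these per-node regressions coincide with joint
ML, and per-node OLS is transparent and directly testable. Total
standardized effects are sums over directed paths to the mortality sink of
products of edge coefficients; the thermal total includes both the
temperature → bleaching → mortality product and the direct temperature
edge. The default DAG encodes: SSC → {mortality, light, sedimentation},
light → mortality, sedimentation → {mortality, sediment cover (massive
only)}, sediment cover → mortality (massive only), temperature →
{bleaching, mortality}, bleaching → mortality. Temperature → light edges
are deliberately absent. Branching corals were never observed with sediment
on their surfaces, so the branching DAG omits the sediment-cover node.

## Scenario composition and interaction classification

Per parameter draw *d* (draws of the three sub-models paired by index —
the sub-models are fitted independently, and a reshuffled pairing is
available as an option), expected loss is evaluated at (31 °C, 8.8 mol
photons) for thermal-alone, (25 °C, L) for dredging-alone and (31 °C, L)
for cumulative, composing bleaching, incidence and conditional loss through
the two-branch pathway expectation. For massive corals the sedimentation
covariate at each grid light is supplied by a monotone log-linear regression
of interval worst-case sedimentation on log worst-case light, slope
constrained non-positive and predictions clipped to [0, 1]. The additive
curve is thermal-alone + dredging-alone, clipped at 1 (the behaviour above a
proportion of 1 being otherwise undefined).

`p_synergy(L)` / `p_antagonism(L)` are the fractions of draws with positive /
negative interaction (exact zeros count toward neither). Thresholds:

* **peak antagonism** — grid argmax of `p_antagonism`; plateaus at the
  maximum are broken toward the most negative median interaction (the
  probability saturates at 1 over wide light ranges, making the raw argmax
  a tie). Its interval comes from the per-draw argmin of the interaction.
* **crossover** — the light at which the *median* interaction changes sign,
  linearly interpolated between bracketing grid points, lowest-light
  crossing if several; per-draw crossovers give the interval. An alternative
  definition (p_synergy crossing 0.5) is exposed by the per-light output
  columns.

Two structural facts constrain interpretation. First, at the high-light
anchor the cumulative and thermal-alone scenarios coincide, so
`interaction(L_high) = −loss_dredging(L_high)` identically — every draw is
non-positive there, whatever the truth. Second, any baseline risk *b* at
benign conditions (25 °C, high light) biases the interaction by −*b*,
because the additive construction counts it twice. The additive-null
calibration therefore uses a truth with hazards additive on the probability
scale and *zero* risk at the scenario anchors, and asserts the
no-false-certainty band on the grid below the anchor; its draw noise is
multiplicative (logit-scale), as additive probability noise is clipped at
zero and systematically removes positive-interaction draws.

## Effect distance

Predicted fortnightly loss per site × interval — observed worst-case light
and sedimentation, temperature replaced by the 31 °C or 25 °C scenario value
— is modelled as a binomial response of starting cover (100 trials,
successes = round(100 × loss)) against a k = 5 smooth of log distance, with
site and fortnight random intercepts. Under the high-thermal scenario only
December–February intervals are used (thermal stress is a summer
phenomenon). ED at level λ (default 0.5) is the smallest distance at which
the curve drops below `min + λ·(max_at_closest − min)`, interpolated
linearly in log distance; the minimum is the curve minimum, which falls at
the farthest distance for monotone curves and at intermediate distances in
the non-monotone branching case. A curve that never drops below the target
reports the ED as absent. Per-draw curves give the interval.

## Synthetic-data generator

The generator is the exact inverse of the fitted models, with every
parameter exposed for recovery tests:

* **Water quality.** Plume pressure `p(d) = A·exp(−d/λ)` with amplitude
  A = 3 (optical depths at the source) and length scale λ = 2 km, chosen so
  near sites (0.19 km) reach the severe low-light conditions observed in
  such monitoring (worst-case DLI ≈ 0.2–0.5 mol photons m⁻² d⁻¹) while far
  sites (> 24 km) are effectively unaffected. Ambient DLI 7 ± 2.5 seasonal,
  floor 0.3; daily lognormal pressure noise (σ = 0.25). PAR is a 12-h diel
  half-sinusoid scaled to each day's DLI. Turbidity is baseline 0.5 NTU
  plus 8 NTU per pressure unit with lognormal noise, plus rare sensor
  artefacts (spikes, small negative excursions) that exercise the screening
  rules. The sedimentation index is ambient 0.05 plus `1 − exp(−p)`,
  clipped to [0, 1]. Temperature is 26.5 ± 2.5 °C seasonal (summer peak
  mid-January) with a +3 °C, 7-day warm anomaly at the seasonal peak —
  a week of unusually warm water — all configurable.
* **Bleaching.** A smooth soft-threshold gate: logistic in thermal excess
  multiplied by logistic ramps at T_gate = 29 °C (width 0.5) and
  L_gate = 4 mol photons m⁻² d⁻¹ (width 0.8); the gated phenomenon is what
  matters, not a hard indicator, and the smooth form avoids fitting
  pathologies. Massive corals carry a −1 logit offset (lower bleaching
  susceptibility than branching).
* **Incidence.** Logit = intercept + low-light stress slope × exp(−L/1)
  + temperature slope × (T − 27) + sedimentation slope × sed (massive only)
  + bleached offset, plus persistent site (SD 0.3) and colony (SD 0.5)
  random intercepts drawn once per site/colony. Defaults: branching
  intercept −3.5, low-light slope 3.5, temperature slope 0.3, bleached
  offset +1.5; massive −3.8 / 2.5 / 0.2 / sed slope 2.0 / offset +0.8.
  These produce bleached-branching incidence of roughly 30–50% and strong
  low-light mortality — the qualitative regime the analysis targets.
* **Loss.** Beta draws with mean 0.10 (branching) or 0.04 (massive),
  bleached multiplier 1.3 (+30%), precisions 8 and 12.
* **Scores.** Cumulative mortality is accumulated continuously and emitted
  through the inverse midpoint binning, so small losses may not register as
  score changes — exactly the discretization a real scorer introduces.
  Bleaching scores rise to category 4 on an event and recover over
  subsequent surveys. A small fraction of colonies (2%) is excluded partway
  (dislodged), exercising the exclusion rules. The latent event table
  (true probabilities, events, continuous losses) is available for
  calibration tests.

What the generator does **not** emulate: spatial correlation of plumes
beyond the distance decay (no direction, tides or weather), instrument
drift, scorer disagreement, colony growth or recovery of dead tissue, and
taxonomic structure beyond the two morphological groups. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
form at these sample sizes — not that any particular field dataset meets
the models' assumptions.

## Problem sizes and reproducibility

Default study conditions: 17 sites spanning 0.19–32.8 km (6 near < 1.5 km,
6 intermediate 4–15 km, 5 far 24–32.8 km), 530 days at 10-minute cadence,
fortnightly surveys (38 per site, within the 27–40 of the design), 10
branching and 23 massive colonies per site, 1000 Monte-Carlo draws. The
test suite and demo runs use reduced sizes (6–12 sites, 120–420 days,
50–400 draws) chosen so the full suite completes in a few minutes while
keeping every statistical check at the stated replicate counts. All
stochastic stages take explicit seeds; identical configurations reproduce
byte-identical data products and manifest checksums (figures excluded from
the determinism contract).

## Known limitations

* The uncertainty engine is a normal approximation, not MCMC; coverage is
  approximate for strongly non-quadratic likelihoods (e.g. near-separated
  bleaching data, where the ridge fallback engages).
* AICc counts one parameter per random-effect SD and treats binomial cells
  as observations; comparisons are only made between models fitted to
  identical rows.
* The crossover threshold from a statistically refitted pipeline carries
  sampling noise of a few tenths of a mol photon; grid-resolution precision
  applies to threshold extraction on known curves, not to refits.
* The logit-link incidence model is intrinsically non-additive on the
  probability scale, so under genuinely probability-additive truth the
  classifier's verdict reflects link misspecification once effects are
  large; the calibration suite therefore works in the rare-event regime.
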