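# Methods

## Model structure

`ckdflow` implements a deterministic compartmental ("stock and flow")
model of chronic kidney disease in a national adult (40+) population.
States: CKD stages 3a, 3b, 4, 5 — defined by KDIGO eGFR bands [45, 60),
[30, 45), [15, 30), [0, 15) ml/min/1.73 m² — then ESKD (on renal
replacement treatment, i.e. haemodialysis or peritoneal dialysis;
transplantation is out of scope) and death. Transitions run strictly
forward, one stage at a time; death is reachable from every living state
and absorbing. Stocks are real-valued person counts, not integer agents;
the model is linear (degree-1 homogeneous) in stocks and inflow.

Within each stage the stock carries three progression classes fixed at
entry:

| class  | definition                        | eGFR decline (ml/min/1.73 m²/yr) |
|--------|-----------------------------------|----------------------------------|
| slow   | no diabetes                       | 1.4                              |
| medium | diabetes, no increased albuminuria| 3.0                              |
| fast   | diabetes + increased albuminuria  | 5.0                              |

Class shares at initialization and for entrants are `fast = dm·alb`,
`medium = dm·(1−alb)`, `slow = 1−dm`, treating diabetes and albuminuria
as independent within a stage (no joint table is available; a
correlation hook would be the natural extension). Because class encodes
diabetes status, the diabetic sub-stock of any stage is its medium+fast
count; progressing individuals keep class and diabetes status, and
stage-specific albuminuria proportions act only at entry.

## Annual transition fractions from the eGFR density

The cross-sectional density of eGFR values below 60 is modelled as
exponential: an OLS fit of ln(count) on the discrete eGFR values 1–59
(zero-count bins dropped — their logarithm is undefined) gives
ln y = a + b·x, default (a, b) = (−0.0556, 0.077). With a constant
annual decline d, the individuals within d of a stage's lower bound exit
during the year:

    f(d) = expm1(b·d) / expm1(b·(U−L)),   f = d/(U−L) when b = 0,

clipped to 1 for d ≥ U−L. This "uniform sweep" of a static within-stage
density is the unique memoryless one-year rule consistent with the
fitted cross-section; it depends on the band only through its width
(a direct consequence of the exponential form), so all four 15-wide
bands share the same fractions: 0.0524 (slow), 0.1196 (medium), 0.2161
(fast) at b = 0.077. The implementation uses `expm1`, making the b → 0
limit continuous to machine precision.

## Cycle order and inflow

Each cycle applies, in order: (1) mortality in every living state,
(2) progression of survivors, (3) incident stage-3a inflow. Entrants
are therefore first exposed to death and progression in their first full
year, avoiding same-year compounding; the alternative order
(`cycle_order: progression_first`) is a config switch for sensitivity.

Inflow is `incidence_population × (1+g)^t × incidence`, with the
incidence 1330 per million population per year and g = 1%/yr adult
growth. The per-million rate is referred to the total national
population (`incidence_population`, default 19 458 310, the 2021
national projection): the published projection's growth (+293 k cases
over 20 years against ~10–12 k deaths/yr) is only attainable with
entrants of that magnitude (~26 k/yr), not with the rate applied to the
40+ base population (~9 k/yr). A separate diabetes-specific incidence
parameter is carried in the config but unused by default, since no
combination rule with the general rate is available.

## Mortality

General-population annual death probability: the per-1000 age-band rates
are averaged with a fixed 40+ age-weight vector and converted by
p₀ = 1 − exp(−rate). Stage- and diabetes-specific hazard ratios act on
the hazard scale, p = 1 − (1−p₀)^HR, which equals scaling the implied
constant hazard and stays in [0, 1] for any HR > 0. The model does not
age individuals; the age-weight vector (a plausible, slowly declining
40+ age structure summing to 1, from 16% at 40–44 to 0.2% at 100+) is a
fixed modelling choice applied to all stages, set once and exposed in
the config.

ESKD mortality has no published hazard ratio and is a direct annual
probability. It is the model's one calibrated constant: chosen so the
20-year growth of the baseline ESKD stock matches the published
projection endpoint, giving 0.004/yr, and frozen in the default config
with a ±20% CI for the PSA. This value is far below observed dialysis
mortality; it compensates for RRT inflow that the lower-bound-crossing
rule keeps smaller than the published model's (see Limitations), and
should be read as a calibration constant, not an epidemiological
estimate.

## Initialization

The default configuration seeds the 2021 stage stocks directly with the
projection's first-year counts (3a 260 935, 3b 105 803, 4 43 597,
5 7 329; ESKD 24 601) — the calibration anchor. These counts are
mutually inconsistent with any single base population under the
published stage prevalences (3.8/1.0/0.8/0.1%), so prevalence-based
initialization (prevalence × 6 866 711, the base population anchored to
the stage-3a count) is available by removing `initial_stage_counts` from
the config, and the registry ESKD seed (22 310 + 1 318) is
config-selectable. In the PSA, prevalence draws scale the seeded counts
proportionally, so initial-condition uncertainty propagates either way.

## Costs

Per-state annual cost = count × per-patient stage cost, plus the
diabetes add-on on the diabetic sub-stock of every state including ESKD,
plus scenario treatment costs (SGLT2 on diabetic 3a/3b; pre-dialysis on
all of stages 4 and 5 — treated as strictly additional to standard stage
costs). Costs are evaluated on start-of-year stocks, making the first
model year a pure function of the initial condition, and discounted by
1/(1+r)^t with r = 3%/yr and t = 0 in the first year ("applied after the
first year").

## Scenarios

Treatment hazard ratios modify annual exit probabilities on the hazard
scale, p → 1 − (1−p)^HR (multiplicative scaling `min(HR·p, 1)` is a
config switch; for the probabilities involved the difference is < 2%).
Uptake among the eligible is 100% (`rrt_uptake` similarly defaults to
full RRT uptake of stage-5 exits). Only progression is modified —
no mortality effect is attributed to either treatment.

## Probabilistic sensitivity analysis

Each uncertain parameter carries (mean, 95% CI, family):

* **Beta** (proportions, probabilities): moment matching with
  σ = (hi − lo)/3.92; infeasible CIs (σ² ≥ m(1−m)) are rejected.
* **Normal** (hazard ratios): μ = mean, σ = (hi − lo)/3.92, draws floored
  at 10⁻⁶. A mean-centred normal cannot represent the asymmetry of the
  published HR intervals (e.g. 0.71, CI 0.57–0.89), so sampled
  percentiles recover μ ± 1.96σ, not the printed endpoints — both ends
  sit ~0.02 low for the SGLT2 HR. The beta moment match does capture
  prevalence-CI asymmetry.
* **Gamma** (costs): σ from the ±20% CI rule, shape = m²/σ²
  (= (1.96/0.2)² ≈ 96.04 under the default rule), scale = σ²/m.

Parameters shared across cells (the SGLT2 HR applies to stages 3a and
3b) receive one common draw. Each iteration draws every non-degenerate
parameter, rebuilds schedule, mortality, initial stocks and cost table,
and reruns the projection; summaries are pointwise means and percentile
(2.5, 97.5) uncertainty intervals. Streams are spawned per iteration
from the master seed (`numpy` `SeedSequence`), so results are
bitwise-reproducible and independent of iteration order. Note that
percentile bands estimated from very few iterations are biased narrow
and widen toward the true quantile span as iterations grow; what shrinks
with more iterations is the Monte Carlo error of each summary.

## Synthetic data

`synthetic.gen_egfr_histogram` draws counts exp(a + b·x + ε),
ε ~ N(0, σ), on the discrete grid 1–59 — exactly the structure the
density fit assumes, so the noiseless round trip recovers (a, b) to
machine precision. `synthetic.gen_survey` generates survey-style records
(eGFR, diabetes, albuminuria, age band): stage membership from the stage
prevalences, within-stage eGFR from the truncated exponential density by
inverse-CDF, flags Bernoulli with the stage's proportions, independent
given stage. `estimate_parameters` returns unweighted proportions with
normal-approximate CIs. The generator deliberately omits complex survey
design (strata, clusters, weights), non-response and
serum-creatinine measurement error — passing recovery tests shows the
estimators are consistent under the model's own assumptions, not that
design-based survey estimation is reproduced.

## Problem sizes used in the test suite

Unit and property tests run the full 20-cycle projection (instantaneous)
and sampling checks at 10⁶ draws. The PSA reproduction test uses 500
iterations (the full 10 000 takes under a minute and is exercised via
the CLI at the user's choice); synthetic-data recovery uses 10⁶ records.

## Known limitations

* The stage-5 → RRT flow derived from the lower-bound-crossing rule is
  slower than the published projection implies (their stage-5 stock
  stays ~3× smaller than this model's). The calibrated ESKD survival
  absorbs part of this; stage-5 counts and the intervention's cost
  savings remain conservative relative to the published tables.
* Published cost tables imply an RRT unit cost ~4% below the printed
  per-patient value used here, so cost totals run correspondingly hot
  even where case counts match.
* No ageing dynamics, CKD stages 1–2, transplantation, cardiovascular
  comorbidity events, or indirect costs; constant rates throughout the
  horizon; parameter draws are uncorrelated.
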