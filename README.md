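# ckdflow

Stock-and-flow projection of the chronic kidney disease (CKD) burden and
its direct healthcare costs in the Chilean population aged 40 and older,
over a 20-year horizon (2021–2041), for health-economic planning.

The model tracks six mutually exclusive states — CKD stages 3a, 3b, 4
and 5 (KDIGO eGFR bands 45–59, 30–44, 15–29, <15 ml/min/1.73 m²),
end-stage kidney disease on renal replacement treatment (ESKD/RRT), and
death — in one-year cycles with strictly forward transitions. Within
each stage the stock is split into three progression classes by
comorbidity: no diabetes (eGFR decline 1.4 ml/min/1.73 m²/yr), diabetes
without increased albuminuria (3), and diabetes with increased
albuminuria (5).

## The model in brief

**Transitions.** The standing population below eGFR 60 follows a
log-linear density fitted by OLS, ln *y* = *a* + *b x* (default
*a* = −0.0556, *b* = 0.077). With annual decline *d* inside a stage band
[*L*, *U*), the fraction crossing the lower bound each year is

    f(d) = (e^{b(L+d)} − e^{bL}) / (e^{bU} − e^{bL})  =  expm1(bd) / expm1(b(U−L)),

clipped to 1 when *d* ≥ *U* − *L* and reducing to *d*/(*U*−*L*) as
*b* → 0. Stage-5 crossings start RRT.

**Mortality.** An age-weighted all-cause death probability
*p₀* = 1 − exp(−Σ wᵢ rᵢ) is adjusted per stage and diabetes status on
the hazard scale, *p* = 1 − (1 − p₀)^HR. Death is absorbing.

**Inflow.** Incident stage-3a cases enter each cycle:
1330 per million population per year, growing with the adult population
at 1%/yr, split across progression classes by the diabetes (31.2%) and
albuminuria (35.5%) proportions.

**Costs.** Annual per-patient direct costs per stage (GBP: 48.76 /
48.76 / 66.73 / 990.12 / 12 044.48 for ESKD) plus a diabetes add-on
(51.37) on diabetic sub-stocks, evaluated on start-of-year stocks and
discounted at 3%/yr after the first year.

**Scenarios.** Baseline, and an intervention adding SGLT2 inhibitors for
diabetic stage 3a/3b (progression HR 0.71, +179.94 GBP/pt/yr) plus
pre-dialysis care in stages 4–5 (HR 0.85, +360.97 and +1637.46).

**Uncertainty.** Probabilistic sensitivity analysis: every parameter with
a 95% CI gets a sampling distribution (Beta for proportions by moment
matching, Normal for hazard ratios, Gamma for costs with a ±20% CI),
10 000 Monte Carlo projections by default, percentile (2.5–97.5)
uncertainty intervals.

## Worked example

```python
import ckdflow as ck

params, costs = ck.load_parameters()          # packaged defaults
baseline = ck.run_projection(params, costs)   # 20 one-year cycles

print(baseline.counts.loc[[2021, 2041], ["3a", "ESKD", "total_ckd"]].round(0))
print((baseline.cost_totals.loc[[2021, 2041]] / 1e6).round(1))
```

prints

```
            3a     ESKD  total_ckd
year
2021  260935.0  24601.0   442265.0
2041  320201.0  83905.0   736638.0
       total  total_discounted
year
2021   331.4             331.4
2041  1097.7             607.8
```

i.e. the modelled CKD population (stages 3a–ESKD) grows from 442 265
persons in 2021 to about 737 000 in 2041; the RRT population more than
triples to about 84 000; annual direct costs rise from 331 M GBP to about
1.1 B GBP (608 M GBP in 2021 present value). The intervention scenario
(`ck.intervention_scenario(params, costs)`) slows progression: fewer
stage-5/ESKD cases but a slightly larger — and cheaper per-patient —
total CKD population.

A command-line interface wraps the same pipeline:

```sh
ckdflow --scenario all --psa --iterations 10000 --seed 7 --outdir out/
```

writing tidy cases/costs CSVs, five-year summary tables, PSA summaries
with uncertainty intervals, and a reproducibility manifest.

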