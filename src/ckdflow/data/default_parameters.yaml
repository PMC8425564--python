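# Default parameter registry for the Chilean CKD burden projection.
#
# Epidemiological inputs (prevalences, albuminuria, diabetes, incidence,
# mortality, hazard ratios) are the published national-survey / registry /
# literature values; costs are the published annual per-patient direct
# costs in GBP.  Two quantities the sources do not pin down are model
# calibration choices and documented in docs/methods.md: the 40+ age-band
# weights and the annual ESKD (RRT) death probability.

model:
  start_year: 2021
  horizon_years: 20
  discount_rate: 0.03
  cycle_order: mortality_first     # mortality -> progression -> inflow
  rrt_uptake: 1.0                  # fraction of stage-5 exits that start RRT
  hr_scale: hazard                 # treatment HRs applied as 1-(1-p)^HR

population:
  # 40+ base population anchored so that 3.8% of it equals the 2021
  # stage-3a stock of 260,935.
  base_population_40plus: 6866711
  # Denominator of the per-million-population incidence rate: the total
  # Chilean population (INE 2021 projection).
  incidence_population: 19458310
  adult_growth_rate: 0.01
  # Age composition of the 40+ population (proportions, sum to 1).
  age_weights:
    40-44: 0.160
    45-49: 0.145
    50-54: 0.135
    55-59: 0.130
    60-64: 0.115
    65-69: 0.095
    70-74: 0.075
    75-79: 0.055
    80-84: 0.040
    85-89: 0.028
    90-94: 0.015
    95-99: 0.005
    100+: 0.002

epidemiology:
  stage_prevalence:                # proportion of the 40+ population
    3a: {mean: 0.038, ci_low: 0.029, ci_high: 0.049, family: beta}
    3b: {mean: 0.010, ci_low: 0.007, ci_high: 0.014, family: beta}
    4:  {mean: 0.008, ci_low: 0.004, ci_high: 0.014, family: beta}
    5:  {mean: 0.001, ci_low: 0.001, ci_high: 0.002, family: beta}
  # First-model-year stocks (the 2021 calibration anchor).  Remove this
  # block to initialize from stage_prevalence x base_population_40plus.
  initial_stage_counts:
    3a: 260935
    3b: 105803
    4: 43597
    5: 7329
  # RRT stock seed; the registry alternative (HD 22310 + PD 1318 = 23628)
  # can be configured here instead.
  esrd_initial_count: 24601
  albuminuria_by_stage:            # proportion with increased albuminuria
    3a: {mean: 0.355, ci_low: 0.257, ci_high: 0.468, family: beta}
    3b: {mean: 0.444, ci_low: 0.304, ci_high: 0.595, family: beta}
    4:  {mean: 0.770, ci_low: 0.470, ci_high: 0.927, family: beta}
    5:  {mean: 1.0, ci_low: 1.0, ci_high: 1.0, family: fixed}
  dm_prevalence_ckd: {mean: 0.312, ci_low: 0.222, ci_high: 0.418, family: beta}
  # Annual incidence of CKD stage 3a, per million population.
  incidence_3a_pmp: {mean: 1330, ci_low: 1253, ci_high: 1412, family: beta}
  # Incidence among adults with diabetes (config hook, not used by the
  # default inflow).
  dm_incidence: {mean: 0.0325, ci_low: 0.022, ci_high: 0.043, family: beta}

progression:
  decline_rates:                   # annual eGFR decline, ml/min/1.73m2
    slow: 1.4
    medium: 3.0
    fast: 5.0
  # Fitted log-linear eGFR density ln(count) = a + b * eGFR.
  egfr_intercept: -0.0556
  egfr_slope: 0.077

mortality:
  rates_per_1000:                  # all-cause, general population
    40-44: 1.43
    45-49: 2.2
    50-54: 3.4
    55-59: 5.4
    60-64: 7.9
    65-69: 12.2
    70-74: 21.2
    75-79: 33.6
    80-84: 55.2
    85-89: 94.5
    90-94: 146.3
    95-99: 228.2
    100+: 260.6
  hr_no_dm:                        # all-cause mortality HR vs eGFR 90-104
    3a: {mean: 1.19, ci_low: 1.10, ci_high: 1.29, family: normal}
    3b: {mean: 1.53, ci_low: 1.36, ci_high: 1.73, family: normal}
    4:  {mean: 2.27, ci_low: 1.86, ci_high: 2.77, family: normal}
    5:  {mean: 4.06, ci_low: 3.33, ci_high: 4.95, family: normal}
  hr_dm:
    3a: {mean: 1.18, ci_low: 1.07, ci_high: 1.30, family: normal}
    3b: {mean: 1.65, ci_low: 1.48, ci_high: 1.83, family: normal}
    4:  {mean: 2.28, ci_low: 1.91, ci_high: 2.72, family: normal}
    5:  {mean: 4.46, ci_low: 3.26, ci_high: 6.10, family: normal}
  # Annual death probability on RRT; calibration knob (no published HR),
  # set once so the 20-year growth of the baseline RRT population matches
  # the published projection endpoint (see docs/methods.md).
  esrd_annual_probability: {mean: 0.004, ci_low: 0.0032, ci_high: 0.0048, family: beta}

costs:
  # Annual per-patient cost in GBP.  Bare numbers receive the +-20% CI
  # (gamma family) used by the probabilistic sensitivity analysis.
  annual_by_stage:
    3a: 48.76
    3b: 48.76
    4: 66.73
    5: 990.12
    ESKD: 12044.48
  dm_addon: 51.37
  sglt2: 179.94
  predialysis_stage4: 360.97
  predialysis_stage5: 1637.46

scenarios:
  # Progression hazard ratios of the intervention scenario.
  sglt2_hr: {mean: 0.71, ci_low: 0.57, ci_high: 0.89, family: normal}
  predialysis_hr: {mean: 0.85, ci_low: 0.74, ci_high: 0.98, family: normal}
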