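# Default parameter set for the microhealth simulator.
#
# Provenance, per coefficient:
#   * the nine cross-effect / education coefficients in the transition
#     blocks marked "published estimate" reproduce logit-scale estimates
#     reported in the European ageing-panel literature for these models
#     (obesity/depression/hypertension/activity education effects and the
#     activity/depression lagged cross-effects);
#   * everything else is ILLUSTRATIVE: chosen to give realistic prevalences,
#     trajectories and mortality levels for a European 50+ population, not
#     estimated from data.  Re-estimate from your own panel with the
#     estimation module before drawing substantive conclusions.

population:
  n_individuals: 10000
  start_year: 2011
  seed: 0
  hm_sigma: 0.5
  # low-education share ~0.70 for pre-1930 cohorts, <0.30 for 1956-60
  education_low_intercept: -0.269
  education_low_slope: -0.0558
  education_ref_year: 1945
  education_medium_share: 0.55
  imputation_models:
    smoker:
      intercept: -1.2
      covariate_betas: {female: -0.40, education_low: 0.15, age_c50: -0.030}
    active:
      intercept: -0.2
      covariate_betas: {female: -0.20, education_low: -0.40, education_medium: -0.15,
                        age_c50: -0.035, smoker: -0.20}
    obese:
      intercept: -1.6
      covariate_betas: {female: 0.05, education_low: 0.50, education_medium: 0.20,
                        age_c50: -0.005, active: -0.30}
    hypertension:
      intercept: -1.0
      covariate_betas: {education_low: 0.30, education_medium: 0.10,
                        age_c50: 0.035, obese: 0.60}
    depressed:
      intercept: -1.8
      covariate_betas: {female: 0.55, education_low: 0.50, education_medium: 0.20,
                        age_c50: 0.015, active: -0.30, smoker: 0.20, obese: 0.10,
                        hypertension: 0.10}
  hm_imputation:
    intercept: 1.30
    covariate_betas: {age_c50: -0.035, education_low: -0.35, education_medium: -0.15,
                      female: -0.05, smoker: -0.10, active: 0.20, obese: -0.15,
                      hypertension: -0.15, depressed: -0.35}

transitions:
  # P(factor=1 at t | state at t-1); beta2_lag is the own-lag persistence.
  smoker:
    # purely autoregressive: no education or other-factor effects
    beta0: -4.3
    beta1_duration: 0.0
    beta2_lag: 6.6
    covariate_betas: {female: -0.10}
    age_spline: {knots: [50, 60, 75, 90], values: [0.0, -0.2, -0.6, -1.2]}
  active:
    beta0: -2.2
    beta1_duration: 0.0
    beta2_lag: 3.6
    covariate_betas:
      education_low: -0.244      # published estimate
      education_medium: -0.10
      smoker: -0.261             # published estimate
      obese: -0.333              # published estimate
      depressed: -0.399          # published estimate
      female: -0.15
    age_spline: {knots: [50, 60, 75, 90], values: [0.0, -0.2, -0.8, -1.8]}
  obese:
    beta0: -3.5
    beta1_duration: 0.0
    beta2_lag: 6.5
    covariate_betas:
      education_low: 0.692       # published estimate
      education_medium: 0.30
      active: -0.20
      female: 0.05
    age_spline: {knots: [50, 60, 75, 90], values: [0.0, -0.1, -0.4, -1.0]}
  hypertension:
    beta0: -3.2
    beta1_duration: 0.0
    beta2_lag: 7.0
    covariate_betas:
      education_low: 0.313       # published estimate
      education_medium: 0.12
      obese: 0.40
      female: -0.05
    # incidence rises with age, peaks near 75, then declines
    age_spline: {knots: [50, 60, 75, 90], values: [0.0, 0.3, 0.6, 0.3]}
  depressed:
    beta0: -2.5
    beta1_duration: 0.0
    beta2_lag: 3.2
    covariate_betas:
      education_low: 0.493       # published estimate
      education_medium: 0.20
      smoker: 0.197              # published estimate
      obese: 0.125               # published estimate
      active: -0.234             # published estimate
      female: 0.45
    # risk rises with age, particularly after 75
    age_spline: {knots: [50, 60, 75, 90], values: [0.0, 0.1, 0.4, 1.2]}

health_change:
  # yearly change in logit(hm/100); cubic in h = hm/100 makes decline
  # faster from good health
  beta0: -0.005
  beta1: -0.012
  beta2: -0.005
  beta3: -0.015
  covariate_betas:
    smoker: -0.005
    inactive: -0.007             # 1 - active: inactivity is the risk factor
    obese: -0.005
    hypertension: -0.005
    depressed: -0.010
    education_low: -0.020
    education_medium: -0.008
    female: 0.002
  age_spline: {knots: [50, 60, 75, 90], values: [0.0, -0.005, -0.015, -0.030]}

mortality:
  schedule:
    intercept: -6.2              # logit q at age 50, male, high education
    slope_age: 0.105
    sex_shifts: {male: 0.0, female: -0.40}
    education_shifts: {low: 0.25, medium: 0.10, high: 0.0}
    year_trend: -0.01            # longevity keeps improving
    ref_year: 2011
    max_age: 110
  contrast:
    cutpoints: [30, 60]          # bad < 30 <= medium < 60 <= good
    raw_betas: {bad: 1.10, medium: 0.45, good: 0.0}

engine:
  start_year: 2011
  horizon_year: 2060
  outcome_window: [2015, 2060]
  nylp_reference_year: 2015
  good_health_threshold: 60.0
  master_seed: 0
  crn_mode: true
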