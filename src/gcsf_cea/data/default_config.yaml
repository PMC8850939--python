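# Base-case configuration: G-CSF primary-prophylaxis cost-effectiveness model.
# All costs are 2019 CNY. Probabilities are per cycle unless noted.

chemotherapy_model:
  p_fn_peg: 0.0116                      # per-cycle FN risk, long-acting arm
  p_fn_rhg: 0.0404                      # per-cycle FN risk, short-acting arm
  p_infection_given_fn_peg: 0.0547
  p_infection_given_fn_rhg: 0.547
  p_death_fn: 0.034                     # case fatality of FN without infection
  p_death_infection: 0.034              # case fatality of infection after FN
  cost_gcsf_peg_per_cycle: 3315.74      # CNY per cycle
  cost_gcsf_rhg_per_cycle: 734.34       # CNY per 6-day course (one per cycle)
  cost_docetaxel_per_vial: 1792.74      # CNY per 20 mg / 0.5 ml vial
  docetaxel_vial_mg: 20.0
  docetaxel_dose_mg_per_m2: 75.0
  cost_cyclophosphamide_per_vial: 120.75  # CNY per 0.2 g vial
  cyclophosphamide_vial_mg: 200.0
  cyclophosphamide_dose_mg_per_m2: 600.0
  cost_fn_inpatient: 25000.0            # CNY per FN admission
  cost_infection_given_fn: 50000.0      # CNY per infection episode
  cost_hospitalization_per_cycle: 14811.10
  utility_chemotherapy: 0.70
  utility_fn: 0.33
  utility_infection: 0.33
  n_chemo_cycles: 4
  chemo_cycle_weeks: 3.0
  body_surface_area_m2: 1.6
  chemo_discount_rate: 0.0

post_chemotherapy_model:
  p_rdi_low_if_fn: 0.500                # P(RDI<85%) with an FN history (measured)
  p_rdi_low_no_fn_lt65: 0.247           # P(RDI<85%), age<65, no FN
  rr_rdi_low_age_ge65: 1.380            # RR of RDI<85% for age>=65 vs <65
  or_rdi_low_fn: 1.580                  # OR of RDI<85%, FN vs no FN
  hr_mortality_rdi_low: 1.730           # mortality HR, RDI<85% vs >=85%
  utility_years_1_5: 0.86
  utility_years_gt5: 0.96
  postchemo_discount_rate: 0.05
  horizon_years: 35
  start_age: 45.0

switches:
  equalize_infection_risk: false
  rdi_or_mode: false
  course_level_fn: false
  half_cycle_correction: false

analysis:
  wtp_per_qaly: 72371.0                 # 2020 GDP per capita

# Synthetic retrospective cohort (five-hospital, TC chemotherapy, women 18+).
cohort:
  n_peg: 926
  n_rhg: 898
  los_mean_peg: 10.47
  los_sd_peg: 7.47
  los_mean_rhg: 8.95
  los_sd_rhg: 7.88
  cost_mean_peg: 17079.0
  cost_sd_peg: 3084.0
  cost_mean_rhg: 14086.0
  cost_sd_rhg: 335.0
  age_mean_peg: 48.80
  age_sd_peg: 9.56
  age_mean_rhg: 48.75
  age_sd_rhg: 9.96
  surgery_rate_peg: 0.529
  surgery_rate_rhg: 0.40
  insurance_categories:
    urban_rural_resident: 0.70
    urban_employee: 0.22
    self_pay: 0.08
  concomitant_disease_rates:            # P(number of concomitant diseases = k)
    0: 0.55
    1: 0.25
    2: 0.13
    3: 0.07
  confound_age_shift: 0.0               # +years added to PEG ages (confounded mode)
  confound_insurance_shift: 0.0         # prevalence mass moved to urban_employee in PEG

# Synthetic life table: Gompertz all-cause mortality calibrated to a target
# life expectancy at birth, plus stage-blended breast-cancer-specific excess
# mortality that decays after year 5 post diagnosis.
life_table:
  gompertz_slope: 0.09
  life_expectancy_at_birth: 80.0
  max_age: 110
  bc_mortality_stage2: 0.010            # annual probability, first 5 years
  bc_mortality_stage3: 0.022
  bc_mortality_stage4: 0.060
  stage_weight_stage2: 0.50
  stage_weight_stage3: 0.35
  stage_weight_stage4: 0.15
  bc_decay_after_years: 5
  bc_decay_rate: 0.15                   # exponential decay per year after year 5

# Probabilistic sensitivity analysis. Explicitly parameterized distributions
# below; every other probability/utility gets a moment-matched beta and every
# cost a moment-matched gamma with SE = default_se_fraction * mean.
psa:
  default_se_fraction: 0.15
  explicit:
    p_rdi_low_if_fn: {kind: beta, alpha: 191, beta: 191}
    p_rdi_low_no_fn_lt65: {kind: beta, alpha: 289, beta: 881}
    utility_years_1_5: {kind: beta, alpha: 40, beta: 6}
    utility_years_gt5: {kind: beta, alpha: 367, beta: 15}
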