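# Default model configuration: pharmacist-led PPI deprescribing service versus
# usual care in ambulatory PPI users aged >= 65, one-year horizon, public
# healthcare provider perspective (Hong Kong; all monetary values in USD at
# USD 1 = HKD 7.8).
#
# Each uncertain parameter carries its base-case value, the range explored in
# sensitivity analysis, and the distribution family used in probabilistic
# sensitivity analysis.  Parameters without a range (unit fees) are fixed.

clinical:
  # Prevalence of inappropriate PPI use among older ambulatory PPI users.
  p_inappropriate: {base: 0.7852, low: 0.7393, high: 0.8405, dist: beta}
  # Mix of deprescribing recommendations issued for inappropriate use
  # (must sum to 1 at base case).
  p_rec_discontinue: {base: 0.3279, low: 0.2951, high: 0.3607, dist: beta}
  p_rec_dosedown: {base: 0.2225, low: 0.2003, high: 0.2448, dist: beta}
  p_rec_switch: {base: 0.4496, low: 0.4046, high: 0.4945, dist: beta}
  # Prescriber acceptance of each recommendation type.
  p_accept_discontinue: {base: 0.7310, low: 0.6579, high: 0.8041, dist: beta}
  p_accept_dosedown: {base: 0.7030, low: 0.6327, high: 0.7733, dist: beta}
  p_accept_switch: {base: 0.8800, low: 0.7920, high: 0.9680, dist: beta}
  # GERD rebound after each deprescribing action (triggers reinstatement).
  p_rebound_discontinue: {base: 0.7867, low: 0.7080, high: 0.8653, dist: beta}
  p_rebound_dosedown: {base: 0.2051, low: 0.1846, high: 0.2256, dist: beta}
  p_rebound_switch: {base: 0.4258, low: 0.3832, high: 0.4683, dist: beta}
  # Yearly adverse-event rates in non-PPI users (baseline risks).
  p0_hypomag: {base: 0.0689, low: 0.0620, high: 0.0758, dist: beta}
  p0_pneumonia: {base: 0.0537, low: 0.0483, high: 0.0591, dist: beta}
  p0_cdi: {base: 0.0408, low: 0.0367, high: 0.0448, dist: beta}
  # Odds ratios for standard-dose PPI users versus non-users.
  or_ppi_hypomag: {base: 1.775, low: 1.077, high: 2.924, dist: triangular}
  or_ppi_pneumonia: {base: 1.490, low: 1.160, high: 1.920, dist: triangular}
  or_ppi_cdi: {base: 2.150, low: 1.810, high: 2.550, dist: triangular}
  # Odds ratios for low-dose PPI users versus non-users.
  or_lowppi_hypomag: {base: 1.775, low: 1.077, high: 2.924, dist: triangular}
  or_lowppi_pneumonia: {base: 1.173, low: 1.110, high: 1.239, dist: triangular}
  or_lowppi_cdi: {base: 1.280, low: 0.940, high: 1.740, dist: triangular}
  # Care-setting and case-fatality branches.
  p_hosp_hypomag: {base: 0.0000131, low: 0.0000118, high: 0.0000144, dist: beta}
  p_hosp_pneumonia: {base: 0.3393, low: 0.3054, high: 0.3732, dist: beta}
  p_mort_cdi: {base: 0.0880, low: 0.0792, high: 0.0968, dist: beta}
  p_mort_pneumonia: {base: 0.1100, low: 0.0990, high: 0.1210, dist: beta}

utility:
  age_years: {base: 80, low: 65, high: 88, dist: triangular}
  utility_age65plus: {base: 0.810, low: 0.729, high: 0.891, dist: triangular}
  # Disutility of symptomatic GERD relapse (rebound episode).
  disutil_relapse_on_meds: {base: 0.0486, low: 0.0, high: 0.405, dist: triangular}
  disutil_relapse_off_meds: {base: 0.0737, low: 0.0, high: 0.567, dist: triangular}
  # Disutility of adverse-event health states.
  disutil_hosp_hypomag: {base: 0.2430, low: 0.1130, high: 0.3730, dist: triangular}
  disutil_hosp_pneumonia: {base: 0.5597, low: 0.5022, high: 0.6164, dist: triangular}
  disutil_amb_pneumonia: {base: 0.3013, low: 0.2649, high: 0.3370, dist: triangular}
  disutil_cdi: {base: 0.3985, low: 0.3587, high: 0.4384, dist: triangular}
  # Time spent in each health state.
  los_hypomag_days: {base: 6, low: 4, high: 9, dist: triangular}
  los_pneumonia_days: {base: 9.8, low: 9.3, high: 10, dist: triangular}
  los_cdi_days: {base: 8, low: 5, high: 14, dist: triangular}
  convalescence_pneumonia_days: {base: 31, low: 13, high: 55, dist: triangular}
  outpatient_pneumonia_days: {base: 31, low: 13, high: 55, dist: triangular}

cost:
  # Monthly drug-acquisition costs (USD).
  cost_ppi_standard_monthly: {base: 54, low: 47, high: 65, dist: gamma}
  cost_ppi_low_monthly: {base: 42, low: 38, high: 47, dist: gamma}
  cost_h2ra_monthly: {base: 6, low: 1.7, high: 10, dist: gamma}
  # Public healthcare unit fees (no range published; fixed in SA and PSA).
  cost_hosp_per_day: {base: 654}
  cost_clinic_visit: {base: 57}
  n_clinic_visits_pneumonia: {base: 3, low: 2, high: 4, dist: triangular}
  # Deprescribing service: pharmacist salary and time per case.
  pharmacist_salary_monthly: {base: 10918, low: 7358, high: 14478, dist: gamma}
  deprescribe_minutes_per_case: {base: 34, low: 28, high: 40, dist: triangular}

run:
  discount_rate_annual: 0.03
  wtp_threshold_usd: 49023
  rebound_onset_days: 20
  # 22 working days x 8 h x 60 min.
  pharmacist_working_minutes_per_month: 10560
  # Remaining life expectancy by age (years), approximating the Hong Kong
  # 2022 life table averaged over sexes; linearly interpolated at the
  # (possibly sampled) cohort age.  Set `remaining_life_expectancy_years`
  # instead to force a single value regardless of age.
  life_table:
    65: 21.3
    70: 17.2
    75: 13.5
    80: 10.1
    85: 7.3
    90: 5.1
    95: 3.5
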