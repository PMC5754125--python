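# Base case: cohort enters at age 50, 25-year horizon, 80% equipment
# utilization, reference salaries. All clinical and cost inputs at their
# point estimates (2013 USD).
name: base_case
config:
  start_age: 50
  horizon: 25
  cohort_size: 1000
  discount_rate: 0.03
  utilization_rate: 0.80
  salary_multiplier: 1.0
  csme_prp_fraction: 0.62
  eyes_per_session: 1.6
  apply_eyes_per_session: false
  treatment_cost_timing: every_cycle
  half_cycle: none
  wtp_threshold: 679.0
  visit_schedule:
    NO_DR: [1, 0, 0]
    MILD_NPDR: [1, 0, 0]
    MODERATE_NPDR: [1, 0, 0]
    SNPDR_PDR: [1, 3, 2]
    CSME: [1, 1, 2]
    SVI: [0, 0, 0]
transitions:
  no_to_mild: [0.21, 0.16, 0.25]
  mild_to_moderate: [0.06, 0.03, 0.09]
  moderate_to_severe: [0.11, 0.02, 0.25]
  severe_to_svi_untreated: [0.09, 0.07, 0.12]
  severe_to_svi_treated: [0.02, 0.00, 0.07]
  csme_to_svi_untreated: [0.05, 0.03, 0.08]
  csme_to_svi_treated: [0.03, 0.00, 0.09]
  rr_mortality: [1.97, 1.17, 2.88]
initial_distribution:
  no_dr: [0.44, 0.41, 0.48]
  mild: [0.30, 0.27, 0.33]
  moderate: [0.09, 0.07, 0.11]
  severe: [0.04, 0.02, 0.05]
  csme: [0.13, 0.11, 0.15]
utilities:
  no_dr: [0.89, 0.78, 0.96]
  mild: [0.80, 0.73, 0.86]
  moderate: [0.80, 0.73, 0.86]
  severe: [0.70, 0.63, 0.76]
  csme: [0.70, 0.63, 0.76]
  svi: [0.55, 0.46, 0.63]
  disability_weight: [0.191, 0.129, 0.269]
costs:
  currency: USD_2013
  exchange_rate_mkw_per_usd: 364.4
  reference_utilization: 0.80
  screening: {staff: 2.77, buildings: 0.17, equipment: 0.09, consumables: 0.72}
  laser_treatment: {staff: 2.14, buildings: 0.77, equipment: 10.76, consumables: 0.48}
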