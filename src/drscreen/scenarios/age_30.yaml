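# Cohort enters at age 30; 38-year horizon (life expectancy at 30).
# The age-window (25-35 y) baseline state distribution was never published,
# so this scenario reuses the base-case distribution and is flagged as an
# approximation; supply your own via initial_distribution to replace it.
name: age_30
extends: base_case
config:
  start_age: 30
  horizon: 38
  initial_distribution_approximate: true
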