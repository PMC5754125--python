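# Staff salaries increased by 20% relative to the base case.
name: salary_plus20
extends: base_case
config:
  salary_multiplier: 1.2
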