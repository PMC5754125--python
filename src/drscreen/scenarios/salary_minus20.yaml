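# Staff salaries reduced by 20% relative to the base case.
name: salary_minus20
extends: base_case
config:
  salary_multiplier: 0.8
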