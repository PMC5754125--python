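# Equipment service utilization lowered from 80% to 50%; per-patient
# equipment costs scale by 0.8/0.5 = 1.6.
name: utilization_50
extends: base_case
config:
  utilization_rate: 0.5
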