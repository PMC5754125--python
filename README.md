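# drscreen

A cohort Markov model of **targeted photographic screening plus laser
photocoagulation for sight-threatening diabetic retinopathy (STDR) and
clinically significant macular edema (CSME)**, evaluated against a
no-screening, no-treatment comparator in a low-income, Malawian hospital
setting. The package computes per-patient provider costs (2013 USD), QALYs
gained, DALYs averted, years of severe visual impairment avoided and the
resulting incremental cost-effectiveness ratios (ICERs) for five service
delivery scenarios, with a probabilistic sensitivity analysis (PSA) and
cost-effectiveness acceptability curves (CEACs).

It is written for health economists and modellers who want a transparent,
scriptable re-implementation of this class of screening decision model.

## The model

A cohort of 1 000 diabetic patients enters at age 50 (base case) distributed
across six health states — no DR, mild NPDR, moderate NPDR, severe NPDR/PDR,
CSME, severe visual impairment (SVI, acuity < 6/60) — plus an explicit dead
state. Annual cycles; movement is strictly forward:

```
NO_DR → MILD → MODERATE → SNPDR/PDR → SVI        CSME → SVI        any live state → DEAD
```

Each cycle, death (probability `q = 1 − exp(−m·RR)`, with `m` the age-band
all-cause mortality rate and `RR = 1.97` the diabetes mortality relative
risk) competes with progression: `P(progress) = (1 − q)·p`. The two arms
differ only in the entry probabilities into SVI — treated (0.02 from
SNPDR/PDR, 0.03 from CSME) in the screened arm versus untreated (0.09, 0.05)
in the comparator.

Screened patients accrue visit costs by state (ingredient costing: staff,
buildings, equipment, consumables): one screening visit per year in
NO_DR/MILD/MODERATE; screening + 3 laser sessions + 2 follow-ups in
SNPDR/PDR; screening + 1 macular laser + 2 follow-ups in CSME, with 62% of
CSME patients also receiving the full scatter-laser course. SVI and the
comparator arm accrue nothing. Equipment costs scale with the inverse
service utilization rate; staff costs scale with salary. Outcomes:

* **QALYs** — discounted person-years weighted by state utilities
  (0.89 / 0.80 / 0.80 / 0.70 / 0.70 / 0.55),
* **DALYs averted** — YLD-only (mortality is arm-independent, so YLLs
  cancel): `0.191 ×` discounted SVI person-years averted,
* **SVI years avoided** — undiscounted,
* **ICER** — Δcost / Δeffect; costs and health effects discounted at 3%/yr.

The PSA draws transition probabilities and utilities from betas fitted by
method of moments to their 95% CIs, the mortality relative risk from a
lognormal, and the baseline state distribution from a fitted Dirichlet;
CEACs report the probability of positive net monetary benefit across
willingness-to-pay thresholds.

## Worked example

```python
from drscreen import run_scenario, bundled_life_table

result = run_scenario("base_case", bundled_life_table())
print(result.rounded_row())
```

prints

```
{'scenario': 'base_case', 'cost_usd': 189, 'incremental_qalys': 0.103,
 'incremental_dalys': 0.132, 'svi_years_avoided': 1.058,
 'icer_per_qaly': 1831, 'icer_per_daly': 1438}
```

Screening and treating one patient for 25 years costs the provider an
expected discounted $189; it buys 0.103 QALYs, averts 0.132 DALYs and avoids
1.06 undiscounted years of severe visual impairment, giving $1 831 per QALY
gained and $1 438 per DALY averted against the no-intervention comparator.

The same pipeline is exposed as a CLI:

```sh
drscreen run-all -o out/                      # five-scenario report (table3.csv/.md)
drscreen run-psa --scenario base_case --n 1000 --seed 42 -o out/
drscreen ceac --samples out/psa_base_case.csv --effect qaly -o out/
drscreen make-synthetic --n 357 --seed 7 -o out/   # registry-style patient data
```

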