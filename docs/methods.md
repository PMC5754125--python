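# Methods

## Model structure

The model is a discrete-time cohort Markov chain with annual cycles over
seven states: five live retinopathy states (no DR, mild NPDR, moderate NPDR,
severe NPDR/PDR, CSME), an absorbing morbid state (severe visual impairment,
SVI — best-corrected acuity < 6/60 in the better eye), and an absorbing dead
state. Permitted arcs are strictly forward along the severity chain, from
SNPDR/PDR and from CSME into SVI, and from every live state to dead. Two
structural simplifications follow the published parameter set rather than
retinal epidemiology:

* **No entry into CSME after baseline.** CSME is populated only by the 13%
  baseline prevalence; no incidence arc is parameterized.
* **No regression.** Laser treatment changes only the probability of
  entering SVI; it never improves a patient's state. SVI is absorbing apart
  from death (a conservative simplification driven by sparse regression
  data).

The intervention (annual photographic screening, laser when indicated) and
comparator (no screening, no treatment) arms share every parameter except
the SVI-entry probabilities: treated 0.02 (SNPDR/PDR) and 0.03 (CSME)
versus untreated 0.09 and 0.05.

## Mortality

All-cause mortality comes from an age-banded life table of central rates
(deaths/person-year, 5-year half-open bands `[lo, hi)`, open-ended final
band). The diabetes-specific relative risk (1.97, 95% CI 1.17–2.88)
multiplies the *hazard*, and the product converts to an annual death
probability under constant hazard: `q(age) = 1 − exp(−m(age)·RR)`. A
simple-product alternative (`min(m·RR, 1)`) is available behind
`mortality_method="product"`; at these rates the two differ by < 2%.

Death is applied first within each cycle and progression is conditioned on
survival (`(1−q)·p`), which keeps rows normalized without rescaling. The
same `q` applies to every live state — no SVI excess mortality — so
survival is identical across arms by construction.

### The bundled life table

The packaged table (`data/malawi_synthetic_lifetable.csv`) is **synthetic**:
a Gompertz hazard `m(age) = A·exp(B·(age − 25))` with `A = 0.0060263`,
`B = 0.0412475`, tabulated at band midpoints in 5-year bands from 25 to
100+. A and B were solved (once, before any model run) so that
general-population remaining life expectancy is exactly 25 years at age 50
and 38 years at age 30 — the two scenario horizons, which were themselves
chosen as age-specific life expectancies. The table approximates the WHO
Malawi table of the study era in level but not in shape (it has no explicit
HIV bulge); any real WHO CSV with the same columns can be passed instead
(`--lifetable`).

## Costs

Ingredient costs per patient-visit (2013 USD), at the 80% reference
utilization rate:

| component   | screening | laser treatment |
|-------------|-----------|-----------------|
| staff       | 2.77      | 2.14            |
| buildings   | 0.17      | 0.77            |
| equipment   | 0.09      | 10.76           |
| consumables | 0.72      | 0.48            |
| total       | 3.75      | 14.15           |

(The treatment components sum to 14.15; the published total is rounded to
14.16. The model uses the component sum.) Unit-cost adjustment:
`staff·salary_multiplier + buildings + equipment·(0.80/utilization) +
consumables` — equipment is a fixed capacity cost spread over the patients
actually served, so only it scales with utilization, and only staff with
salary. Follow-up visits are costed at the screening rate. The average of
1.6 eyes per laser session is carried as metadata and does **not** multiply
the per-session cost (treatment costs are read as per patient-session); an
`apply_eyes_per_session` flag exists for exploration.

**Treatment-cost timing.** Patients in a treatable state at their annual
screening visit receive the full laser/follow-up bundle, which recurs for
every year spent in the state (`treatment_cost_timing="every_cycle"`,
default). A `"first_entry"` policy charging the bundle only once per entry
is implemented. Calibration of this open choice against the published
base-case cost of $209 with the bundled life table gives $189.05 for
`every_cycle` versus $59.46 for `first_entry`, confirming `every_cycle` as
the default (−9.5%, inside a ±10% reproduction band).

Accrual is counted at cycle start with no half-cycle correction
(`half_cycle="none"`); a standard half-cycle average is available and moves
base-case results by < 2%. Nothing accrues after the transition to death,
and SVI patients receive no further care (no cost, no blindness-care costs —
provider perspective only).

## Effectiveness

QALYs weight discounted person-years by state utilities (0.89, 0.80, 0.80,
0.70, 0.70, 0.55 from no DR through SVI; time-trade-off values anchored in
vision). DALYs are **YLD-only**: because mortality is arm-independent, YLL
terms cancel in the increment, leaving `ΔDALY = 0.191 × (discounted SVI
person-years averted)` — an identity the tests assert exactly. "Years of
severe visual impairment avoided" is reported undiscounted; costs, QALYs
and DALYs are discounted at 3%/year from cycle 0.

## Scenarios

Five packaged configurations: base case (age 50, horizon 25 y, utilization
80%, salaries at reference), age 30 (horizon 38 y), salaries ±20%, and
utilization 50%. The age-30 cohort's own baseline state distribution was
never published, so that scenario reuses the base-case distribution and
warns that it is an approximation (it is user-replaceable). The
willingness-to-pay reference is $679 per effect unit (the national
cost-effectiveness threshold used for this setting).

## Probabilistic sensitivity analysis

No distribution families are published, so the package makes the
conventional choices and treats them as assumptions:

* transition probabilities, utilities and the disability weight: beta,
  method of moments with mean = point estimate and sd = (CI width)/3.92;
* mortality relative risk: lognormal, log-median ln(1.97),
  log-sd (ln 2.88 − ln 1.17)/3.92;
* baseline distribution: Dirichlet `α = p·ν` with ν fitted to the widest
  printed marginal CI (no DR, 41–48%), giving ν ≈ 771.7;
* unit costs: fixed (no cost uncertainty is published).

Draws are independent across parameters; in particular the deterministic
bundle's non-increasing-utility ordering is *not* enforced on draws, since
mild/moderate (and severe/CSME) share identical distributions and rejection
would bias every marginal. Range violations (outside [0,1], RR ≤ 0) are
resampled with bounded retries. Each iteration uses the counter-derived
stream `default_rng([seed, iteration])`, so results are order-independent
and reproducible; 1 000 iterations and a $0–2 000 (step 10) threshold grid
are the defaults. CEAC probabilities use the strict net-monetary-benefit
rule `P(λ·Δeffect − Δcost > 0)`.

## Synthetic patient-level data

`drscreen.synthetic` generates registry-style cohorts (default n = 357, two
annual follow-ups) for estimator and pipeline testing: baseline states from
the initial distribution (optionally age-window-specific), annual forward
transitions from true parameters, per-year laser flags in treatable states
(coverage 1.0 by default, as in the source registry where everyone meeting
criteria was treated), optional missing-at-random dropout, and an optional
moderate-NPDR→CSME incidence arc for estimator robustness checks only. Ages
are a clipped normal (mean 54, sd 12) — an assumption, as the registry age
profile is unpublished. The generator does **not** emulate mortality,
visual-acuity measurements, grading error or informative dropout, so
estimator recovery on these cohorts demonstrates statistical correctness of
the estimators, not robustness to real-world measurement processes.
`estimate_transitions` uses observed-transition proportions with Wilson 95%
intervals (inestimable parameters are flagged NaN, never zeroed);
parameter-recovery tests at n = 10 000 recover every probability within
±0.02.

## Reproduction of the published results, and where it fails

With the printed clinical and cost parameters, the specified arc structure
and the bundled life table, the model reproduces (computed by the test
suite and `scripts/acceptance.py`):

* the published ICER arithmetic identities (e.g. 209/0.523 → $400,
  256/0.466 → $549) exactly;
* the base-case per-patient cost within ±10% ($189.05 vs $209);
* every published cross-scenario ordering: age-30 has the lowest ICERs,
  50%-utilization the highest, salaries ±20% bracket the base case (ICERs
  and costs), and the cost-only scenarios share identical effect sizes;
* the PSA ordering of QALY-based acceptance probabilities at λ = $679
  (age 30 > base case > 50% utilization).

It does **not** reproduce the published effect magnitudes: the model yields
0.103 incremental QALYs, 0.132 DALYs averted and 1.058 SVI-years avoided in
the base case, versus published 0.523 / 0.273 / 2.199. Two observations
locate the discrepancy:

1. The model's ratio of discounted to undiscounted SVI-years averted is
   0.651 — identical to the published 1.43/2.199 = 0.650 — so the *timing*
   of SVI accrual matches and only the magnitude of flow into SVI differs,
   by almost exactly a factor of two. The printed transition probabilities
   simply do not generate the published flow under a structure with no
   CSME incidence and no regression; additional unpublished structure (most
   plausibly entry arcs into CSME, consistent with the registry's observed
   STDR incidence) would be needed.
2. Under this structure, conservation forces
   `ΔQALY = (0.70 − 0.55) × discounted SVI-years averted`, so
   ΔQALY/ΔDALY = 0.15/0.191 < 1 always, whereas the published QALY
   increment exceeds the DALY increment (0.523 > 0.273). The published QALY
   gain is therefore not derivable from the printed utilities under any
   parameter choice here; consequently the DALY-based CEAC sits *above*
   the QALY-based one (the published curves show the opposite), and the
   base-case QALY acceptance probability at $679 is near zero rather than
   91%.

These three comparisons are kept as failing assertions in
`tests/test_acceptance.py` rather than being loosened; no generator
parameter, tolerance or seed was adjusted toward the published values.

## Numerical choices

* Transition-matrix rows are validated to sum to 1 within 1e-12; cohort
  mass is conserved within 1e-9 per cycle.
* Age-band lookup is half-open (`age_high` belongs to the next band); ages
  beyond the last closed band use the final band's rate.
* ICERs: Δeffect = 0 yields a tagged "undefined" result, cost-saving
  effective results are "dominant", costlier ineffective ones "dominated",
  and the south-west quadrant keeps its ratio with a label — never an
  exception.
* Trace CSVs round-trip bit-exactly (`float_precision="round_trip"` on
  reload).
* Report rounding: whole dollars for costs and ICERs, three decimals for
  effect increments; a full-precision sidecar CSV accompanies every report.

## Problem sizes

Default runs are small by construction: 7-state matrices over 25–38 cycles,
1 000-iteration PSAs (a few seconds per scenario), 10 000-patient synthetic
cohorts for estimator recovery. These sizes were chosen as the model's own
study conditions; all published-value comparisons use them unchanged.
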