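"""Synthetic patient-level cohorts with the structure of the study's registry data.

The source study followed 357 clinic-sampled diabetic patients for two
years, grading the worse eye annually and treating everyone who met the
laser criteria. This module generates cohorts with that structure — baseline
grade, state at years 1 and 2, a laser-treatment flag per transition year —
and provides the estimators that recover the annual transition probabilities
and the baseline state distribution from such data. It also generates small
geometric life tables for tests.

Cohorts are plain data frames with columns
``patient_id, age, state_y0, state_y1, state_y2, treated_y1, treated_y2``
(states by name, missing after loss to follow-up) and round-trip through CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import InitialDistribution, ParamCI, TransitionParams
from .states import HealthState, PROGRESSION_ARCS, TREATABLE_STATES

COHORT_COLUMNS = ["patient_id", "age", "state_y0", "state_y1", "state_y2", "treated_y1", "treated_y2"]


@dataclass(frozen=True)
class PatientRecord:
    """One participant: baseline grade, two annual follow-ups, treatment flags.

    ``state_y1``/``state_y2`` and the matching treatment flags are ``None``
    after loss to follow-up.
    """

    patient_id: int
    age: float
    state_y0: HealthState
    state_y1: HealthState | None
    state_y2: HealthState | None
    treated_y1: bool | None
    treated_y2: bool | None

    @classmethod
    def from_row(cls, row) -> "PatientRecord":
        def st(x):
            return None if pd.isna(x) else HealthState[x]

        def fl(x):
            return None if pd.isna(x) else bool(x)

        return cls(
            int(row.patient_id), float(row.age), HealthState[row.state_y0],
            st(row.state_y1), st(row.state_y2), fl(row.treated_y1), fl(row.treated_y2),
        )

_INIT_STATES = (
    HealthState.NO_DR,
    HealthState.MILD_NPDR,
    HealthState.MODERATE_NPDR,
    HealthState.SNPDR_PDR,
    HealthState.CSME,
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generator settings; defaults emulate the study cohort (n = 357).

    Ages are drawn from a clipped normal (diabetes-clinic attendees, mean 54,
    sd 12 — an assumption; the registry's age profile is not published).
    ``treatment_coverage`` is the probability a treatable patient actually
    receives laser in a given year (1.0 in the study, where everyone meeting
    criteria was treated). ``loss_to_followup`` is an annual
    missing-at-random dropout fraction. ``incident_csme_prob`` adds a
    moderate-NPDR→CSME arc the cohort model itself does not have; it exists
    only for robustness testing of the estimators.
    """

    n: int = 357
    seed: int = 0
    age_mean: float = 54.0
    age_sd: float = 12.0
    age_min: float = 20.0
    age_max: float = 85.0
    transitions: TransitionParams = field(default_factory=TransitionParams)
    initial: InitialDistribution = field(default_factory=InitialDistribution)
    #: optional ((age_low, age_high), InitialDistribution) pairs; the first
    #: window containing a patient's age overrides the overall distribution
    window_initials: tuple = ()
    loss_to_followup: float = 0.0
    treatment_coverage: float = 1.0
    incident_csme_prob: float = 0.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n!r}")
        for name in ("loss_to_followup", "treatment_coverage", "incident_csme_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


def _initial_for_age(spec: SyntheticCohortSpec, age: float) -> InitialDistribution:
    for (lo, hi), dist in spec.window_initials:
        if lo <= age < hi:
            return dist
    return spec.initial


def _step(
    state: HealthState, treated: bool, tp: TransitionParams, incident_csme: float, rng
) -> HealthState:
    if state is HealthState.SVI:
        return state
    if state is HealthState.SNPDR_PDR:
        p = (tp.severe_to_svi_treated if treated else tp.severe_to_svi_untreated).point
    elif state is HealthState.CSME:
        p = (tp.csme_to_svi_treated if treated else tp.csme_to_svi_untreated).point
    else:
        p = {
            HealthState.NO_DR: tp.no_to_mild.point,
            HealthState.MILD_NPDR: tp.mild_to_moderate.point,
            HealthState.MODERATE_NPDR: tp.moderate_to_severe.point,
        }[state]
    if state is HealthState.MODERATE_NPDR and incident_csme > 0 and rng.random() < incident_csme:
        return HealthState.CSME
    return PROGRESSION_ARCS[state] if rng.random() < p else state


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw one synthetic two-year cohort; reproducible for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    init_probs_cache: dict[int, np.ndarray] = {}
    rows = []
    for pid in range(spec.n):
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), spec.age_min, spec.age_max))
        dist = _initial_for_age(spec, age)
        probs = np.array([getattr(dist, f).point for f in InitialDistribution._FIELDS])
        probs = probs / probs.sum()
        state = _INIT_STATES[rng.choice(len(_INIT_STATES), p=probs)]
        record = {"patient_id": pid, "age": round(age, 1), "state_y0": state.name}
        lost = False
        for year in (1, 2):
            if lost or rng.random() < spec.loss_to_followup:
                lost = True
                record[f"state_y{year}"] = None
                record[f"treated_y{year}"] = None
                continue
            treated = state in TREATABLE_STATES and rng.random() < spec.treatment_coverage
            state = _step(state, treated, spec.transitions, spec.incident_csme_prob, rng)
            record[f"treated_y{year}"] = bool(treated)
            record[f"state_y{year}"] = state.name
        rows.append(record)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    assert_valid_arcs(df)
    return df


def assert_valid_arcs(cohort: pd.DataFrame, allow_incident_csme: bool = True) -> None:
    """Assert every observed year-on-year move uses a permitted arc."""
    allowed = {(s.name, s.name) for s in HealthState} | {
        (a.name, b.name) for a, b in PROGRESSION_ARCS.items()
    }
    if allow_incident_csme:
        allowed.add((HealthState.MODERATE_NPDR.name, HealthState.CSME.name))
    for a, b in (("state_y0", "state_y1"), ("state_y1", "state_y2")):
        pairs = cohort[[a, b]].dropna()
        bad = [t for t in pairs.itertuples(index=False) if (t[0], t[1]) not in allowed]
        if bad:
            raise AssertionError(f"forbidden transitions present: {bad[:5]}")


def wilson_interval(events: int, trials: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if trials == 0:
        return (math.nan, math.nan)
    p = events / trials
    denom = 1.0 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials))
    return (max(0.0, center - half), min(1.0, center + half))


def _estimate(events: int, trials: int) -> ParamCI:
    if trials == 0:
        return ParamCI(math.nan, math.nan, math.nan)  # inestimable, not zero
    lo, hi = wilson_interval(events, trials)
    return ParamCI(events / trials, lo, hi)


def estimate_transitions(cohort: pd.DataFrame) -> TransitionParams:
    """Annual transition probabilities with Wilson 95% CIs from a cohort.

    Each probability is (observed from→to moves) / (person-years at risk in
    the from-state, i.e. observed from-state years with a known next state).
    Entry into severe visual impairment is estimated separately for treated
    and untreated person-years using the per-year treatment flag. A state
    with zero person-years yields NaN bounds (flagged inestimable) rather
    than zero. The mortality relative risk is not identifiable from two-year
    eye data and is returned at its default.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    counts: dict[tuple, list[int]] = {}

    def tally(key: tuple, moved: bool) -> None:
        ev_tr = counts.setdefault(key, [0, 0])
        ev_tr[1] += 1
        ev_tr[0] += int(moved)

    for y_from, y_to, treated_col in (("state_y0", "state_y1", "treated_y1"), ("state_y1", "state_y2", "treated_y2")):
        obs = cohort[[y_from, y_to, treated_col]].dropna(subset=[y_from, y_to])
        for frm, to, treated in obs.itertuples(index=False):
            frm_s, to_s = HealthState[frm], HealthState[to]
            if frm_s in TREATABLE_STATES:
                tally((frm_s, bool(treated)), to_s is HealthState.SVI)
            elif frm_s in PROGRESSION_ARCS:
                tally((frm_s,), to_s is PROGRESSION_ARCS[frm_s])

    def est(key: tuple) -> ParamCI:
        events, trials = counts.get(key, [0, 0])
        return _estimate(events, trials)

    return TransitionParams(
        no_to_mild=est((HealthState.NO_DR,)),
        mild_to_moderate=est((HealthState.MILD_NPDR,)),
        moderate_to_severe=est((HealthState.MODERATE_NPDR,)),
        severe_to_svi_untreated=est((HealthState.SNPDR_PDR, False)),
        severe_to_svi_treated=est((HealthState.SNPDR_PDR, True)),
        csme_to_svi_untreated=est((HealthState.CSME, False)),
        csme_to_svi_treated=est((HealthState.CSME, True)),
    )


def estimate_initial_distribution(
    cohort: pd.DataFrame, age_window: tuple[float, float] | None = None
) -> InitialDistribution:
    """Baseline-state proportions among patients with age in ``[low, high)``.

    Point estimates sum to one; per-state Wilson CIs accompany them.
    """
    df = cohort
    if age_window is not None:
        lo, hi = age_window
        df = cohort[(cohort["age"] >= lo) & (cohort["age"] < hi)]
    if len(df) == 0:
        raise ValueError(f"no patients with enrolment age in window {age_window!r}")
    n = len(df)
    kwargs = {}
    for fname, state in zip(InitialDistribution._FIELDS, _INIT_STATES):
        k = int((df["state_y0"] == state.name).sum())
        lo_ci, hi_ci = wilson_interval(k, n)
        kwargs[fname] = ParamCI(k / n, lo_ci, hi_ci)
    return InitialDistribution(**kwargs)


def generate_life_table(base_rate: float, growth: float = 1.0, bands: int = 13) -> LifeTable:
    """Geometric synthetic life table: 5-year bands from age 25, final band open.

    ``rate_k = base_rate * growth**k``; useful as a controlled stand-in for a
    national table in tests.
    """
    if base_rate <= 0:
        raise ValueError(f"base_rate must be > 0, got {base_rate!r}")
    if growth < 1.0:
        raise ValueError(f"growth must be >= 1, got {growth!r}")
    if bands < 1:
        raise ValueError("need at least one band")
    lows = 25.0 + 5.0 * np.arange(bands)
    highs = lows + 5.0
    highs[-1] = np.inf
    rates = base_rate * growth ** np.arange(bands)
    return LifeTable(lows, highs, rates)
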