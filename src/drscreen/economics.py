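"""Costs, QALYs, DALYs, and incremental cost-effectiveness ratios.

The comparator (no screening, no treatment) accrues no provider cost, so the
incremental cost equals the intervention arm's discounted per-patient cost.
QALYs weight each discounted person-year by its health-state utility. DALYs
here are YLD-only: mortality is identical across arms, so years of life lost
cancel in the increment and the DALYs averted reduce to

    dDALY = disability_weight * (discounted SVI person-years averted).

"Years of severe visual impairment avoided" is reported undiscounted;
costs, QALYs and DALYs are discounted (3%/year by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace
from .parameters import ScenarioConfig, UtilityParams
from .states import Arm, HealthState, LIVE_STATES


def _cost_parts(
    state: HealthState, cfg: ScenarioConfig, screening_cost: float, treatment_cost: float
) -> tuple[float, float]:
    """(per-cycle screening component, per-entry/per-cycle treatment component)."""
    sched = cfg.visit_schedule[state]
    screening_part = sched.screening * screening_cost
    treatment_part = sched.laser * treatment_cost + sched.followup * screening_cost
    if state is HealthState.CSME:
        # 62% of macular-edema patients also receive the full scatter-laser
        # course given for SNPDR/PDR
        prp_sessions = cfg.visit_schedule[HealthState.SNPDR_PDR].laser
        treatment_part += cfg.csme_prp_fraction * prp_sessions * treatment_cost
    return screening_part, treatment_part


def cycle_cost_per_state(
    state: HealthState,
    arm: Arm,
    cfg: ScenarioConfig,
    screening_cost: float,
    treatment_cost: float,
) -> float:
    """Provider cost of one person-cycle spent in ``state``.

    Follow-up visits are costed at the screening-visit rate. The comparator
    arm accrues nothing; severe visual impairment receives no further care.
    """
    if arm is Arm.COMPARATOR or state is HealthState.DEAD:
        return 0.0
    screening_part, treatment_part = _cost_parts(state, cfg, screening_cost, treatment_cost)
    return screening_part + treatment_part


@dataclass(frozen=True)
class ArmResult:
    """Per-patient outcomes of one arm."""

    total_discounted_cost: float
    discounted_qalys: float
    discounted_svi_years: float
    undiscounted_svi_years: float


@dataclass(frozen=True)
class ICER:
    """An incremental cost-effectiveness ratio, or the quadrant label that
    replaces it when a ratio is not meaningful.

    Labels: ``ratio`` (NE quadrant), ``dominant`` (cheaper and at least as
    effective), ``dominated`` (costlier, no more effective), ``southwest``
    (cheaper but less effective; the ratio is reported and must be read as a
    savings-per-effect-lost trade-off), ``undefined`` (zero effect difference).
    """

    label: str
    ratio: float = math.nan

    @property
    def value(self) -> float:
        return self.ratio


def icer(delta_cost: float, delta_effect: float) -> ICER:
    if delta_effect == 0.0:
        return ICER("undefined")
    if delta_effect > 0:
        if delta_cost <= 0:
            return ICER("dominant", delta_cost / delta_effect)
        return ICER("ratio", delta_cost / delta_effect)
    if delta_cost > 0:
        return ICER("dominated")
    return ICER("southwest", delta_cost / delta_effect)


@dataclass(frozen=True)
class ScenarioResult:
    """One scenario's incremental results (intervention minus comparator)."""

    scenario: str
    cost_per_patient: float
    incremental_qalys: float
    incremental_dalys_averted: float
    svi_years_avoided: float
    icer_per_qaly: ICER
    icer_per_daly: ICER
    intervention: ArmResult
    comparator: ArmResult

    def rounded_row(self) -> dict:
        """Row with report rounding: whole dollars, 3-decimal effects."""
        return {
            "scenario": self.scenario,
            "cost_usd": round(self.cost_per_patient),
            "incremental_qalys": round(self.incremental_qalys, 3),
            "incremental_dalys": round(self.incremental_dalys_averted, 3),
            "svi_years_avoided": round(self.svi_years_avoided, 3),
            "icer_per_qaly": round(self.icer_per_qaly.value) if self.icer_per_qaly.label == "ratio" else self.icer_per_qaly.label,
            "icer_per_daly": round(self.icer_per_daly.value) if self.icer_per_daly.label == "ratio" else self.icer_per_daly.label,
        }


def _occupancy_basis(trace: CohortTrace, cfg: ScenarioConfig) -> np.ndarray:
    """Per-cycle state membership used for accrual, cycles 0..horizon-1."""
    occ = trace.occupancy
    if cfg.half_cycle == "standard":
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def arm_outcomes(
    trace: CohortTrace,
    cfg: ScenarioConfig,
    utilities: UtilityParams,
    screening_cost: float,
    treatment_cost: float,
) -> ArmResult:
    """Discounted per-patient cost, QALYs and SVI person-years for one arm.

    Costs and effects accrue at cycle start (or as the half-cycle average when
    configured); nothing accrues after the transition to death. Under the
    ``first_entry`` cost-timing policy the laser/follow-up bundle is charged
    only in the cycle a patient enters a treatable state, while the annual
    screening visit is charged for every cycle in state.
    """
    h = trace.horizon
    k = np.arange(h, dtype=float)
    disc = (1.0 + cfg.discount_rate) ** (-k)
    basis = _occupancy_basis(trace, cfg)

    cost = 0.0
    qalys = 0.0
    util = utilities.by_state()
    for state in LIVE_STATES:
        occ_k = basis[:, state]
        qalys += util[state] * float(occ_k @ disc)
        if trace.arm is Arm.INTERVENTION:
            screening_part, treatment_part = _cost_parts(
                state, cfg, screening_cost, treatment_cost
            )
            cost += screening_part * float(occ_k @ disc)
            if cfg.treatment_cost_timing == "first_entry":
                ent_k = trace.entrants[:h, state]
                cost += treatment_part * float(ent_k @ disc)
            else:
                cost += treatment_part * float(occ_k @ disc)

    svi_disc = float(basis[:, HealthState.SVI] @ disc)
    svi_undisc = float(basis[:, HealthState.SVI].sum())
    n = trace.cohort_size
    return ArmResult(cost / n, qalys / n, svi_disc / n, svi_undisc / n)


def incremental_result(
    intervention: ArmResult,
    comparator: ArmResult,
    disability_weight: float,
    scenario: str = "",
) -> ScenarioResult:
    """Combine the two arms into Table-style incremental outcomes."""
    delta_cost = intervention.total_discounted_cost - comparator.total_discounted_cost
    delta_qaly = intervention.discounted_qalys - comparator.discounted_qalys
    svi_years_averted_disc = comparator.discounted_svi_years - intervention.discounted_svi_years
    delta_daly = disability_weight * svi_years_averted_disc
    svi_avoided = comparator.undiscounted_svi_years - intervention.undiscounted_svi_years
    return ScenarioResult(
        scenario=scenario,
        cost_per_patient=delta_cost,
        incremental_qalys=delta_qaly,
        incremental_dalys_averted=delta_daly,
        svi_years_avoided=svi_avoided,
        icer_per_qaly=icer(delta_cost, delta_qaly),
        icer_per_daly=icer(delta_cost, delta_daly),
        intervention=intervention,
        comparator=comparator,
    )
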