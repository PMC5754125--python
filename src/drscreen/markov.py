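"""Transition-matrix construction and cohort propagation.

Each annual cycle, death (at the age-specific probability ``q``) competes
with disease progression: the death arc is applied first and every
progression probability is conditioned on survival, so a live state's row is
``P(DEAD) = q``, ``P(forward arc) = (1 - q) * p``, ``P(stay) = (1 - q) * (1 - p)``.
Rows therefore sum to one without renormalization.

The arm picks which entry probabilities into severe visual impairment apply:
treated (intervention) or untreated (comparator). All other arcs, and
mortality, are identical across arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import LifeTable, annual_death_probability
from .parameters import ScenarioConfig, TransitionParams
from .states import Arm, HealthState, N_STATES

_ROW_SUM_TOL = 1e-12


class MatrixConstructionError(ValueError):
    """A constructed transition-matrix entry fell outside [0, 1]."""


def _progression_probs(tp: TransitionParams, arm: Arm) -> dict[HealthState, float]:
    severe = tp.severe_to_svi_treated if arm is Arm.INTERVENTION else tp.severe_to_svi_untreated
    csme = tp.csme_to_svi_treated if arm is Arm.INTERVENTION else tp.csme_to_svi_untreated
    return {
        HealthState.NO_DR: tp.no_to_mild.point,
        HealthState.MILD_NPDR: tp.mild_to_moderate.point,
        HealthState.MODERATE_NPDR: tp.moderate_to_severe.point,
        HealthState.SNPDR_PDR: severe.point,
        HealthState.CSME: csme.point,
    }


def build_transition_matrix(tp: TransitionParams, arm: Arm, q_death: float) -> np.ndarray:
    """One-cycle transition matrix (7x7, row-stochastic) for the given arm.

    ``q_death`` is the annual death probability shared by every live state.
    """
    if not (0.0 <= q_death <= 1.0):
        raise MatrixConstructionError(f"q_death must be in [0, 1], got {q_death!r}")
    from .states import PROGRESSION_ARCS

    M = np.zeros((N_STATES, N_STATES))
    probs = _progression_probs(tp, arm)
    for state in HealthState:
        if state is HealthState.DEAD:
            M[state, state] = 1.0
            continue
        M[state, HealthState.DEAD] = q_death
        p = probs.get(state, 0.0)
        target = PROGRESSION_ARCS.get(state)
        if target is not None:
            M[state, target] = (1.0 - q_death) * p
        M[state, state] += (1.0 - q_death) * (1.0 - p)
    if np.any(M < -0.0) or np.any(M > 1.0 + 1e-15):
        raise MatrixConstructionError("transition matrix entry outside [0, 1]")
    rowsums = M.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > _ROW_SUM_TOL):
        raise MatrixConstructionError(f"row sums deviate from 1: {rowsums}")
    return M


@dataclass
class CohortTrace:
    """State occupancy (person counts) at the start of each annual cycle.

    ``occupancy[k, s]`` is the number of cohort members in state ``s`` at the
    start of cycle ``k`` (k = 0 .. horizon); ``entrants[k, s]`` is the number
    arriving in ``s`` at cycle ``k`` from a different state (cycle 0 entrants
    are the initial occupants).
    """

    occupancy: np.ndarray
    entrants: np.ndarray
    arm: Arm
    start_age: float
    cohort_size: float
    scenario: str = ""

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "age", self.start_age + np.arange(self.occupancy.shape[0]))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, arm: Arm, cohort_size: float | None = None) -> "CohortTrace":
        df = pd.read_csv(path, float_precision="round_trip")  # bit-exact reload
        occ = df[[s.name for s in HealthState]].to_numpy(dtype=float)
        size = cohort_size if cohort_size is not None else float(occ[0].sum())
        # entrants are not serialized; recompute is impossible without the
        # matrices, so a reloaded trace carries zero entrants
        return cls(occ, np.zeros_like(occ), arm, float(df["age"].iloc[0]), size)

    def person_years(self, state: HealthState, discount_rate: float = 0.0) -> float:
        """Discounted person-years in ``state`` over cycles 0..horizon-1 (whole cohort)."""
        k = np.arange(self.horizon)
        weights = (1.0 + discount_rate) ** (-k.astype(float))
        return float(self.occupancy[:-1, state] @ weights)


def run_cohort(
    cfg: ScenarioConfig,
    tp: TransitionParams,
    arm: Arm,
    lt: LifeTable,
    mortality_method: str = "constant_hazard",
) -> CohortTrace:
    """Propagate the cohort over the scenario horizon for one arm.

    Cycle ``k`` runs at age ``start_age + k``; its matrix uses the life-table
    rate at that age multiplied by the diabetes mortality relative risk.
    """
    if not lt.covers(cfg.start_age, cfg.start_age + cfg.horizon):
        raise ValueError(
            f"life table does not cover start age {cfg.start_age!r} "
            f"(table starts at {lt.age_low[0]!r})"
        )
    occ = np.zeros((cfg.horizon + 1, N_STATES))
    ent = np.zeros_like(occ)
    occ[0] = cfg.initial_distribution.as_array() * cfg.cohort_size
    ent[0] = occ[0]
    rr = tp.rr_mortality.point
    for k in range(cfg.horizon):
        q = annual_death_probability(lt.rate_at_age(cfg.start_age + k), rr, mortality_method)
        M = build_transition_matrix(tp, arm, q)
        occ[k + 1] = occ[k] @ M
        off_diag = M - np.diag(np.diag(M))
        ent[k + 1] = occ[k] @ off_diag
    return CohortTrace(occ, ent, arm, cfg.start_age, cfg.cohort_size, cfg.name)
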