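"""Health states and model arms.

The cohort moves through six live states ordered by retinopathy severity —
no retinopathy, mild NPDR, moderate NPDR, severe NPDR/PDR, clinically
significant macular edema (CSME) — plus the absorbing morbid state of severe
visual impairment (best-corrected acuity < 6/60 in the better eye). An
explicit DEAD state does the mortality bookkeeping.

Permitted movement is strictly forward along the severity chain, from
SNPDR/PDR or CSME into severe visual impairment, and from any live state to
DEAD. There is no entry into CSME after baseline and no regression from any
state: severe visual impairment is absorbing apart from death.
"""

from __future__ import annotations

from enum import Enum, IntEnum


class HealthState(IntEnum):
    """Markov health states, ordered by increasing severity."""

    NO_DR = 0
    MILD_NPDR = 1
    MODERATE_NPDR = 2
    SNPDR_PDR = 3
    CSME = 4
    SVI = 5
    DEAD = 6


#: live states (everything except DEAD), in matrix order
LIVE_STATES: tuple[HealthState, ...] = tuple(s for s in HealthState if s is not HealthState.DEAD)

#: states an occupant can progress out of, and where the single forward arc leads
PROGRESSION_ARCS: dict[HealthState, HealthState] = {
    HealthState.NO_DR: HealthState.MILD_NPDR,
    HealthState.MILD_NPDR: HealthState.MODERATE_NPDR,
    HealthState.MODERATE_NPDR: HealthState.SNPDR_PDR,
    HealthState.SNPDR_PDR: HealthState.SVI,
    HealthState.CSME: HealthState.SVI,
}

#: states in which laser treatment is indicated at the screening visit
TREATABLE_STATES: frozenset[HealthState] = frozenset(
    {HealthState.SNPDR_PDR, HealthState.CSME}
)

N_STATES = len(HealthState)


class Arm(Enum):
    """Model arm: screened-and-treated cohort vs. no-intervention cohort."""

    INTERVENTION = "intervention"
    COMPARATOR = "comparator"
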