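"""Model parameters, scenario configuration, and cost-adjustment arithmetic.

Every clinical and cost input of the model lives here: annual transition
probabilities with their 95% CIs, the baseline distribution of the cohort
across health states, health-state utilities and the severe-visual-impairment
disability weight, and the per-visit ingredient costs (staff, buildings,
equipment, consumables; 2013 USD).

Five named scenarios ship as packaged YAML documents (``base_case``,
``age_30``, ``salary_minus20``, ``salary_plus20``, ``utilization_50``); the
four variants extend ``base_case`` and state only the fields they change.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, NamedTuple

import yaml

from .states import HealthState

#: equipment costs in the cost table are defined at this service utilization rate
REFERENCE_UTILIZATION = 0.80

NAMED_SCENARIOS = (
    "base_case",
    "age_30",
    "salary_minus20",
    "salary_plus20",
    "utilization_50",
)


class ValidationError(ValueError):
    """A parameter bundle violates its schema; ``fields`` lists the offenders."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid parameters: " + "; ".join(problems))


class UnknownScenarioError(KeyError):
    """Requested named scenario is not one of the packaged defaults."""


class ParamCI(NamedTuple):
    """A point estimate with its 95% confidence bounds."""

    point: float
    low: float
    high: float

    @property
    def width(self) -> float:
        return self.high - self.low


def _ci(value: Any) -> ParamCI:
    if isinstance(value, ParamCI):
        return value
    if isinstance(value, (int, float)):
        v = float(value)
        return ParamCI(v, v, v)
    point, low, high = (float(x) for x in value)
    return ParamCI(point, low, high)


@dataclass(frozen=True)
class TransitionParams:
    """Annual transition probabilities and the diabetes mortality relative risk.

    Each probability is a :class:`ParamCI` triple. The treated/untreated pairs
    for entry into severe visual impairment carry the laser-treatment effect:
    the intervention arm uses the treated values, the comparator the untreated
    ones. ``rr_mortality`` multiplies the all-cause mortality hazard for every
    live state in both arms.
    """

    no_to_mild: ParamCI = ParamCI(0.21, 0.16, 0.25)
    mild_to_moderate: ParamCI = ParamCI(0.06, 0.03, 0.09)
    moderate_to_severe: ParamCI = ParamCI(0.11, 0.02, 0.25)
    severe_to_svi_untreated: ParamCI = ParamCI(0.09, 0.07, 0.12)
    severe_to_svi_treated: ParamCI = ParamCI(0.02, 0.00, 0.07)
    csme_to_svi_untreated: ParamCI = ParamCI(0.05, 0.03, 0.08)
    csme_to_svi_treated: ParamCI = ParamCI(0.03, 0.00, 0.09)
    rr_mortality: ParamCI = ParamCI(1.97, 1.17, 2.88)

    _PROB_FIELDS = (
        "no_to_mild",
        "mild_to_moderate",
        "moderate_to_severe",
        "severe_to_svi_untreated",
        "severe_to_svi_treated",
        "csme_to_svi_untreated",
        "csme_to_svi_treated",
    )

    def validate(self) -> list[str]:
        problems = []
        for name in self._PROB_FIELDS:
            p: ParamCI = getattr(self, name)
            if not (0.0 <= p.low <= p.point <= p.high <= 1.0):
                problems.append(
                    f"transitions.{name}: require 0 <= low <= point <= high <= 1, got {p}"
                )
        rr = self.rr_mortality
        if not (0.0 < rr.low <= rr.point <= rr.high):
            problems.append(f"transitions.rr_mortality: require 0 < low <= point <= high, got {rr}")
        return problems


@dataclass(frozen=True)
class InitialDistribution:
    """Baseline proportions of the cohort across the five live disease states.

    Severe visual impairment is assumed absent at entry. Point estimates must
    sum to 1 (the CI bounds need not).
    """

    no_dr: ParamCI = ParamCI(0.44, 0.41, 0.48)
    mild: ParamCI = ParamCI(0.30, 0.27, 0.33)
    moderate: ParamCI = ParamCI(0.09, 0.07, 0.11)
    severe: ParamCI = ParamCI(0.04, 0.02, 0.05)
    csme: ParamCI = ParamCI(0.13, 0.11, 0.15)

    _FIELDS = ("no_dr", "mild", "moderate", "severe", "csme")

    _STATE_FOR_FIELD = {
        "no_dr": HealthState.NO_DR,
        "mild": HealthState.MILD_NPDR,
        "moderate": HealthState.MODERATE_NPDR,
        "severe": HealthState.SNPDR_PDR,
        "csme": HealthState.CSME,
    }

    def points(self) -> dict[HealthState, float]:
        return {self._STATE_FOR_FIELD[f]: getattr(self, f).point for f in self._FIELDS}

    def as_array(self):
        import numpy as np

        from .states import N_STATES

        out = np.zeros(N_STATES)
        for state, p in self.points().items():
            out[state] = p
        return out

    def validate(self) -> list[str]:
        problems = []
        total = 0.0
        for name in self._FIELDS:
            p: ParamCI = getattr(self, name)
            if p.point < 0 or p.low < 0:
                problems.append(f"initial_distribution.{name}: negative proportion {p}")
            total += p.point
        if abs(total - 1.0) > 1e-9:
            problems.append(f"initial_distribution: point estimates sum to {total!r}, not 1")
        return problems


@dataclass(frozen=True)
class UtilityParams:
    """Health-state utilities (time-trade-off, anchored in vision) and the
    GBD disability weight for severe visual impairment.

    Utilities must be non-increasing along the severity chain; the disability
    weight applies only to person-years lived with severe visual impairment.
    """

    no_dr: ParamCI = ParamCI(0.89, 0.78, 0.96)
    mild: ParamCI = ParamCI(0.80, 0.73, 0.86)
    moderate: ParamCI = ParamCI(0.80, 0.73, 0.86)
    severe: ParamCI = ParamCI(0.70, 0.63, 0.76)
    csme: ParamCI = ParamCI(0.70, 0.63, 0.76)
    svi: ParamCI = ParamCI(0.55, 0.46, 0.63)
    disability_weight: ParamCI = ParamCI(0.191, 0.129, 0.269)

    _STATE_FIELDS = ("no_dr", "mild", "moderate", "severe", "csme", "svi")

    def by_state(self) -> dict[HealthState, float]:
        order = (
            HealthState.NO_DR,
            HealthState.MILD_NPDR,
            HealthState.MODERATE_NPDR,
            HealthState.SNPDR_PDR,
            HealthState.CSME,
            HealthState.SVI,
        )
        return {s: getattr(self, f).point for s, f in zip(order, self._STATE_FIELDS)}

    def validate(self) -> list[str]:
        problems = []
        for name in self._STATE_FIELDS + ("disability_weight",):
            p: ParamCI = getattr(self, name)
            if not (0.0 <= p.low <= p.point <= p.high <= 1.0):
                problems.append(f"utilities.{name}: require values in [0, 1] with low<=point<=high, got {p}")
        chain = [getattr(self, f).point for f in self._STATE_FIELDS]
        if any(a < b - 1e-12 for a, b in zip(chain, chain[1:])):
            problems.append("utilities: not non-increasing along the severity chain")
        return problems


@dataclass(frozen=True)
class CostComponents:
    """Ingredient costs of one patient-visit, 2013 USD."""

    staff: float
    buildings: float
    equipment: float
    consumables: float

    def total(self) -> float:
        return self.staff + self.buildings + self.equipment + self.consumables

    def validate(self, label: str) -> list[str]:
        return [
            f"costs.{label}.{f.name}: negative cost {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
            if getattr(self, f.name) < 0
        ]


#: Table of per-visit hospital costs; equipment components are per-patient
#: figures defined at the 80% reference utilization rate.
@dataclass(frozen=True)
class CostTable:
    screening: CostComponents = CostComponents(2.77, 0.17, 0.09, 0.72)
    laser_treatment: CostComponents = CostComponents(2.14, 0.77, 10.76, 0.48)
    reference_utilization: float = REFERENCE_UTILIZATION
    currency: str = "USD_2013"
    exchange_rate_mkw_per_usd: float = 364.4  # metadata only

    def validate(self) -> list[str]:
        problems = self.screening.validate("screening") + self.laser_treatment.validate(
            "laser_treatment"
        )
        if not (0 < self.reference_utilization <= 1):
            problems.append(
                f"costs.reference_utilization: must be in (0, 1], got {self.reference_utilization!r}"
            )
        return problems


def adjusted_visit_cost(
    components: CostComponents,
    salary_multiplier: float = 1.0,
    utilization_rate: float = REFERENCE_UTILIZATION,
    reference_utilization: float = REFERENCE_UTILIZATION,
) -> float:
    """Per-visit cost after salary and equipment-utilization scaling.

    Staff costs scale linearly with ``salary_multiplier``. The per-patient
    equipment cost is a fixed annual cost spread over the patients actually
    served, so it scales with ``reference_utilization / utilization_rate``
    (halving utilization doubles the per-patient equipment cost). Buildings
    and consumables never scale.
    """
    if utilization_rate <= 0:
        raise ValueError(f"utilization_rate must be > 0, got {utilization_rate!r}")
    return (
        components.staff * salary_multiplier
        + components.buildings
        + components.equipment * (reference_utilization / utilization_rate)
        + components.consumables
    )


class VisitSchedule(NamedTuple):
    """Annual visit counts for an occupant of one health state."""

    screening: int
    laser: int
    followup: int


DEFAULT_VISIT_SCHEDULE: dict[HealthState, VisitSchedule] = {
    HealthState.NO_DR: VisitSchedule(1, 0, 0),
    HealthState.MILD_NPDR: VisitSchedule(1, 0, 0),
    HealthState.MODERATE_NPDR: VisitSchedule(1, 0, 0),
    HealthState.SNPDR_PDR: VisitSchedule(1, 3, 2),
    HealthState.CSME: VisitSchedule(1, 1, 2),
    HealthState.SVI: VisitSchedule(0, 0, 0),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one evaluation scenario.

    ``treatment_cost_timing`` selects whether occupants of a treatable state
    accrue the laser/follow-up bundle every cycle they spend in the state
    (``"every_cycle"``, default) or only in the cycle they enter it
    (``"first_entry"``). ``half_cycle`` selects the membership correction
    (``"none"`` counts occupancy at cycle start; ``"standard"`` averages
    start- and end-of-cycle occupancy).
    """

    name: str = "base_case"
    start_age: float = 50.0
    horizon: int = 25
    cohort_size: float = 1000.0
    discount_rate: float = 0.03
    utilization_rate: float = 0.80
    salary_multiplier: float = 1.0
    csme_prp_fraction: float = 0.62
    eyes_per_session: float = 1.6  # metadata; multiplies laser cost only if enabled
    apply_eyes_per_session: bool = False
    treatment_cost_timing: str = "every_cycle"
    half_cycle: str = "none"
    wtp_threshold: float = 679.0
    visit_schedule: dict[HealthState, VisitSchedule] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_SCHEDULE)
    )
    initial_distribution: InitialDistribution = field(default_factory=InitialDistribution)
    initial_distribution_approximate: bool = False

    def validate(self) -> list[str]:
        problems = []
        if self.horizon < 1:
            problems.append(f"config.horizon: must be >= 1, got {self.horizon!r}")
        if self.cohort_size < 1:
            problems.append(f"config.cohort_size: must be >= 1, got {self.cohort_size!r}")
        if not (0 < self.utilization_rate <= 1):
            problems.append(
                f"config.utilization_rate: must be in (0, 1], got {self.utilization_rate!r}"
            )
        if self.discount_rate < 0:
            problems.append(f"config.discount_rate: must be >= 0, got {self.discount_rate!r}")
        if self.salary_multiplier < 0:
            problems.append(f"config.salary_multiplier: must be >= 0, got {self.salary_multiplier!r}")
        if not (0 <= self.csme_prp_fraction <= 1):
            problems.append(
                f"config.csme_prp_fraction: must be in [0, 1], got {self.csme_prp_fraction!r}"
            )
        if self.treatment_cost_timing not in ("every_cycle", "first_entry"):
            problems.append(
                "config.treatment_cost_timing: must be 'every_cycle' or 'first_entry', "
                f"got {self.treatment_cost_timing!r}"
            )
        if self.half_cycle not in ("none", "standard"):
            problems.append(f"config.half_cycle: must be 'none' or 'standard', got {self.half_cycle!r}")
        missing = [s.name for s in HealthState if s is not HealthState.DEAD and s not in self.visit_schedule]
        if missing:
            problems.append(f"config.visit_schedule: missing states {missing}")
        problems += self.initial_distribution.validate()
        return problems


@dataclass(frozen=True)
class ModelInputs:
    """A fully validated parameter bundle for one scenario."""

    config: ScenarioConfig
    transitions: TransitionParams
    utilities: UtilityParams
    costs: CostTable

    def validate(self) -> list[str]:
        return (
            self.config.validate()
            + self.transitions.validate()
            + self.utilities.validate()
            + self.costs.validate()
        )

    def screening_visit_cost(self) -> float:
        """Unit cost of a screening (= follow-up) visit under this scenario."""
        return adjusted_visit_cost(
            self.costs.screening,
            self.config.salary_multiplier,
            self.config.utilization_rate,
            self.costs.reference_utilization,
        )

    def treatment_visit_cost(self) -> float:
        """Unit cost of one laser session under this scenario."""
        cost = adjusted_visit_cost(
            self.costs.laser_treatment,
            self.config.salary_multiplier,
            self.config.utilization_rate,
            self.costs.reference_utilization,
        )
        if self.config.apply_eyes_per_session:
            cost *= self.config.eyes_per_session
        return cost


# ---------------------------------------------------------------------------
# YAML scenario loading

def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _read_scenario_doc(source: str | Path) -> dict:
    path = Path(source)
    if path.suffix in (".yaml", ".yml", ".json") or path.exists():
        if not path.exists():
            raise FileNotFoundError(path)
        doc = yaml.safe_load(path.read_text())
    else:
        name = str(source)
        if name not in NAMED_SCENARIOS:
            raise UnknownScenarioError(
                f"unknown scenario {name!r}; packaged scenarios are {NAMED_SCENARIOS}"
            )
        text = resources.files("drscreen").joinpath(f"scenarios/{name}.yaml").read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValidationError([f"scenario document {source!r} is not a mapping"])
    parent = doc.pop("extends", None)
    if parent is not None:
        doc = _deep_merge(_read_scenario_doc(parent), doc)
    return doc


def _apply_overrides(doc: dict, overrides: dict[str, Any] | None) -> dict:
    if not overrides:
        return doc
    doc = _deep_merge(doc, {})
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        if len(parts) == 1:  # bare keys address the config block
            parts = ["config", parts[0]]
        node = doc
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return doc


def _build_inputs(doc: dict) -> ModelInputs:
    cfg_doc = dict(doc.get("config", {}))
    schedule = {
        HealthState[name]: VisitSchedule(*counts)
        for name, counts in (cfg_doc.pop("visit_schedule", None) or {}).items()
    } or dict(DEFAULT_VISIT_SCHEDULE)

    init_doc = doc.get("initial_distribution")
    init = (
        InitialDistribution(**{k: _ci(v) for k, v in init_doc.items()})
        if init_doc
        else InitialDistribution()
    )
    config = ScenarioConfig(
        name=doc.get("name", "custom"),
        visit_schedule=schedule,
        initial_distribution=init,
        **cfg_doc,
    )
    trans_doc = doc.get("transitions")
    transitions = (
        TransitionParams(**{k: _ci(v) for k, v in trans_doc.items()})
        if trans_doc
        else TransitionParams()
    )
    util_doc = doc.get("utilities")
    utilities = (
        UtilityParams(**{k: _ci(v) for k, v in util_doc.items()}) if util_doc else UtilityParams()
    )
    costs_doc = doc.get("costs")
    if costs_doc:
        costs = CostTable(
            screening=CostComponents(**costs_doc["screening"]),
            laser_treatment=CostComponents(**costs_doc["laser_treatment"]),
            reference_utilization=costs_doc.get("reference_utilization", REFERENCE_UTILIZATION),
            currency=costs_doc.get("currency", "USD_2013"),
            exchange_rate_mkw_per_usd=costs_doc.get("exchange_rate_mkw_per_usd", 364.4),
        )
    else:
        costs = CostTable()
    return ModelInputs(config=config, transitions=transitions, utilities=utilities, costs=costs)


def load_scenario(source: str | Path, overrides: dict[str, Any] | None = None) -> ModelInputs:
    """Load a packaged scenario by name, or a user scenario file, and validate it.

    ``overrides`` maps dotted keys (``"config.discount_rate"``,
    ``"transitions.no_to_mild"``) to replacement values; bare keys address the
    config block. Raises :class:`UnknownScenarioError` for an unrecognized
    name and :class:`ValidationError` (listing every offending field) for a
    schema violation.
    """
    doc = _apply_overrides(_read_scenario_doc(source), overrides)
    inputs = _build_inputs(doc)
    problems = inputs.validate()
    if problems:
        raise ValidationError(problems)
    if inputs.config.initial_distribution_approximate:
        warnings.warn(
            f"scenario {inputs.config.name!r}: its age-window baseline distribution is not "
            "published; using the base-case distribution as an approximation "
            "(override initial_distribution to supply your own)",
            UserWarning,
            stacklevel=2,
        )
    return inputs
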