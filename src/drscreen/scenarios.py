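"""Scenario orchestration: end-to-end runs and the five-scenario report table."""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd

from .economics import ScenarioResult, arm_outcomes, incremental_result
from .lifetable import LifeTable, bundled_life_table
from .markov import CohortTrace, run_cohort
from .parameters import ModelInputs, NAMED_SCENARIOS, load_scenario
from .states import Arm

#: report row order (matches the published scenario ordering)
SCENARIO_ORDER = NAMED_SCENARIOS

#: scenario descriptors shown alongside results
_DESCRIPTORS = {
    "base_case": (50, 80, 100),
    "age_30": (30, 80, 100),
    "salary_minus20": (50, 80, 80),
    "salary_plus20": (50, 80, 120),
    "utilization_50": (50, 50, 100),
}


class ReportError(ValueError):
    """The report was asked for scenarios that were not run."""


def run_arms(
    inputs: ModelInputs, lt: LifeTable | None = None
) -> tuple[CohortTrace, CohortTrace]:
    """Propagate both arms of a scenario; returns (intervention, comparator)."""
    if lt is None:
        lt = bundled_life_table()
    return (
        run_cohort(inputs.config, inputs.transitions, Arm.INTERVENTION, lt),
        run_cohort(inputs.config, inputs.transitions, Arm.COMPARATOR, lt),
    )


def run_scenario(
    source: str | Path | ModelInputs,
    lt: LifeTable | None = None,
    overrides: dict[str, Any] | None = None,
) -> ScenarioResult:
    """Deterministic end-to-end run of one scenario (load → both arms → economics)."""
    inputs = source if isinstance(source, ModelInputs) else load_scenario(source, overrides)
    trace_i, trace_c = run_arms(inputs, lt)
    screening_cost = inputs.screening_visit_cost()
    treatment_cost = inputs.treatment_visit_cost()
    return incremental_result(
        arm_outcomes(trace_i, inputs.config, inputs.utilities, screening_cost, treatment_cost),
        arm_outcomes(trace_c, inputs.config, inputs.utilities, screening_cost, treatment_cost),
        inputs.utilities.disability_weight.point,
        scenario=inputs.config.name,
    )


def run_all_scenarios(
    lt: LifeTable | None = None, overrides: dict[str, Any] | None = None
) -> dict[str, ScenarioResult]:
    """Run the five packaged scenarios in report order."""
    if lt is None:
        lt = bundled_life_table()
    return {name: run_scenario(name, lt, overrides) for name in SCENARIO_ORDER}


def table3_report(
    results: dict[str, ScenarioResult], rounded: bool = True
) -> pd.DataFrame:
    """Assemble the scenario-by-outcome report table.

    One row per scenario in report order, with descriptor columns (cohort
    age, utilization %, salary %) followed by cost, incremental QALYs/DALYs,
    years of severe visual impairment avoided, and the two ICERs. With
    ``rounded=True`` the published rounding conventions apply (whole dollars,
    3-decimal effects); ``rounded=False`` keeps full precision.
    """
    missing = [n for n in results if n in SCENARIO_ORDER and results[n] is None]
    ordered = [n for n in SCENARIO_ORDER if n in results] + [
        n for n in results if n not in SCENARIO_ORDER
    ]
    if missing:
        raise ReportError(f"missing scenario results: {missing}")
    rows = []
    for name in ordered:
        res = results[name]
        age, util, salary = _DESCRIPTORS.get(name, (None, None, None))
        base = {"scenario": name, "cohort_age": age, "utilization_pct": util, "salary_pct": salary}
        if rounded:
            base.update({k: v for k, v in res.rounded_row().items() if k != "scenario"})
        else:
            base.update(
                cost_usd=res.cost_per_patient,
                incremental_qalys=res.incremental_qalys,
                incremental_dalys=res.incremental_dalys_averted,
                svi_years_avoided=res.svi_years_avoided,
                icer_per_qaly=res.icer_per_qaly.value,
                icer_per_daly=res.icer_per_daly.value,
            )
        rows.append(base)
    return pd.DataFrame(rows)


def write_report(
    results: dict[str, ScenarioResult], out_dir: str | Path
) -> dict[str, Path]:
    """Write ``table3.csv``/``table3.md`` (rounded) and a full-precision sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rounded = table3_report(results, rounded=True)
    raw = table3_report(results, rounded=False)
    paths = {
        "csv": out_dir / "table3.csv",
        "md": out_dir / "table3.md",
        "raw": out_dir / "table3_raw.csv",
    }
    rounded.to_csv(paths["csv"], index=False)
    paths["md"].write_text(rounded.to_markdown(index=False) + "\n")
    raw.to_csv(paths["raw"], index=False)
    return paths
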