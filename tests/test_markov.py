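"""Transition-matrix construction and cohort propagation.

The propagation oracle: on a tiny chain over few cycles, exhaustive
enumeration of every state path (multiplying arc probabilities along the
path) must agree with the matrix-product cohort trace to 1e-12.
"""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drscreen import (
    Arm,
    HealthState,
    ParamCI,
    TransitionParams,
    build_transition_matrix,
    run_cohort,
)
from drscreen.markov import CohortTrace, MatrixConstructionError
from drscreen.parameters import InitialDistribution, ScenarioConfig
from drscreen.states import LIVE_STATES, PROGRESSION_ARCS
from drscreen.synthetic import generate_life_table


def _tp(**overrides) -> TransitionParams:
    # toy parameters: unit mortality relative risk so an explicit q_death maps
    # straight onto the life-table rate chosen by the test
    overrides.setdefault("rr_mortality", 1.0)
    fields = {f: ParamCI(v, v, v) for f, v in overrides.items()}
    return dataclasses.replace(TransitionParams(), **fields)


def _uniform_ci(p):
    return ParamCI(p, p, p)


ZERO_TP = _tp(
    no_to_mild=0.0, mild_to_moderate=0.0, moderate_to_severe=0.0,
    severe_to_svi_untreated=0.0, severe_to_svi_treated=0.0,
    csme_to_svi_untreated=0.0, csme_to_svi_treated=0.0,
)


def _config(**kw) -> ScenarioConfig:
    return ScenarioConfig(**kw)


class TestBuildTransitionMatrix:
    def test_untreated_severe_row_without_mortality(self):
        M = build_transition_matrix(TransitionParams(), Arm.COMPARATOR, q_death=0.0)
        s = HealthState.SNPDR_PDR
        assert M[s, HealthState.SVI] == pytest.approx(0.09)
        assert M[s, s] == pytest.approx(0.91)

    def test_treated_probabilities_selected_by_arm(self):
        M = build_transition_matrix(TransitionParams(), Arm.INTERVENTION, q_death=0.0)
        assert M[HealthState.SNPDR_PDR, HealthState.SVI] == pytest.approx(0.02)
        assert M[HealthState.CSME, HealthState.SVI] == pytest.approx(0.03)

    def test_certain_death_sends_all_mass_to_dead(self):
        M = build_transition_matrix(TransitionParams(), Arm.INTERVENTION, q_death=1.0)
        for s in LIVE_STATES:
            assert M[s, HealthState.DEAD] == 1.0

    def test_competing_risk_composition(self):
        M = build_transition_matrix(TransitionParams(), Arm.COMPARATOR, q_death=0.05)
        s = HealthState.SNPDR_PDR
        assert M[s, HealthState.DEAD] == pytest.approx(0.05)
        assert M[s, HealthState.SVI] == pytest.approx(0.95 * 0.09)
        assert M[s, s] == pytest.approx(0.8645)

    def test_invalid_q_death_rejected(self):
        with pytest.raises(MatrixConstructionError):
            build_transition_matrix(TransitionParams(), Arm.COMPARATOR, q_death=1.5)

    @settings(deadline=None, max_examples=50)
    @given(
        q=st.floats(0.0, 1.0),
        probs=st.lists(st.floats(0.0, 1.0), min_size=7, max_size=7),
        arm=st.sampled_from(list(Arm)),
    )
    def test_rows_sum_to_one_and_arcs_respected(self, q, probs, arm):
        names = TransitionParams._PROB_FIELDS
        tp = _tp(**dict(zip(names, probs)))
        M = build_transition_matrix(tp, arm, q)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert M.min() >= 0.0 and M.max() <= 1.0
        # only permitted arcs carry mass
        for i in HealthState:
            for j in HealthState:
                if i == j or j is HealthState.DEAD:
                    continue
                if PROGRESSION_ARCS.get(i) is not j:
                    assert M[i, j] == 0.0
        assert M[HealthState.DEAD, HealthState.DEAD] == 1.0


def enumerate_paths(init: np.ndarray, matrices: list[np.ndarray]) -> np.ndarray:
    """Oracle: occupancy after each cycle by summing over all state paths."""
    n = len(init)
    horizon = len(matrices)
    occ = np.zeros((horizon + 1, n))
    occ[0] = init
    for k in range(1, horizon + 1):
        for path in itertools.product(range(n), repeat=k + 1):
            mass = init[path[0]]
            for step, (a, b) in enumerate(zip(path, path[1:])):
                mass *= matrices[step][a, b]
            occ[k, path[-1]] += mass
    return occ


class TestRunCohort:
    def test_identity_dynamics(self):
        cfg = _config(horizon=1)
        lt = generate_life_table(1e-12, 1.0, 16)
        trace = run_cohort(cfg, ZERO_TP, Arm.COMPARATOR, lt)
        np.testing.assert_allclose(trace.occupancy[1], trace.occupancy[0], atol=1e-6)

    def test_single_step_hand_computation(self):
        init = InitialDistribution(
            no_dr=_uniform_ci(1.0), mild=_uniform_ci(0.0), moderate=_uniform_ci(0.0),
            severe=_uniform_ci(0.0), csme=_uniform_ci(0.0),
        )
        cfg = _config(horizon=1, initial_distribution=init)
        tp = dataclasses.replace(ZERO_TP, no_to_mild=ParamCI(0.21, 0.21, 0.21))
        lt = generate_life_table(1e-15, 1.0, 16)
        trace = run_cohort(cfg, tp, Arm.COMPARATOR, lt)
        assert trace.occupancy[1, HealthState.NO_DR] == pytest.approx(790.0, abs=1e-6)
        assert trace.occupancy[1, HealthState.MILD_NPDR] == pytest.approx(210.0, abs=1e-6)

    def test_mass_conservation_every_cycle(self, base_inputs, life_table):
        for arm in Arm:
            trace = run_cohort(base_inputs.config, base_inputs.transitions, arm, life_table)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-9)

    def test_dead_occupancy_non_decreasing(self, base_inputs, life_table):
        trace = run_cohort(base_inputs.config, base_inputs.transitions, Arm.COMPARATOR, life_table)
        assert np.all(np.diff(trace.occupancy[:, HealthState.DEAD]) >= 0)

    def test_intervention_never_exceeds_comparator_svi(self, base_inputs, life_table):
        ti = run_cohort(base_inputs.config, base_inputs.transitions, Arm.INTERVENTION, life_table)
        tc = run_cohort(base_inputs.config, base_inputs.transitions, Arm.COMPARATOR, life_table)
        assert np.all(ti.occupancy[:, HealthState.SVI] <= tc.occupancy[:, HealthState.SVI] + 1e-12)

    def test_equal_treated_untreated_probs_make_arms_identical(self, base_inputs, life_table):
        tp = dataclasses.replace(
            base_inputs.transitions,
            severe_to_svi_treated=base_inputs.transitions.severe_to_svi_untreated,
            csme_to_svi_treated=base_inputs.transitions.csme_to_svi_untreated,
        )
        ti = run_cohort(base_inputs.config, tp, Arm.INTERVENTION, life_table)
        tc = run_cohort(base_inputs.config, tp, Arm.COMPARATOR, life_table)
        np.testing.assert_array_equal(ti.occupancy, tc.occupancy)

    def test_life_table_coverage_gap_rejected(self, base_inputs):
        lt = generate_life_table(0.01, 1.0, 16)  # starts at 25
        cfg = dataclasses.replace(base_inputs.config, start_age=20.0)
        with pytest.raises(ValueError, match="cover"):
            run_cohort(cfg, base_inputs.transitions, Arm.COMPARATOR, lt)

    @settings(deadline=None, max_examples=15)
    @given(
        p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0), p3=st.floats(0.0, 1.0),
        q=st.floats(0.0, 0.5),
    )
    def test_path_enumeration_oracle(self, p1, p2, p3, q):
        """Matrix propagation equals exhaustive path enumeration (3 cycles)."""
        tp = _tp(no_to_mild=p1, mild_to_moderate=p2, moderate_to_severe=p3)
        matrices = [build_transition_matrix(tp, Arm.COMPARATOR, q)] * 3
        init = InitialDistribution(
            no_dr=_uniform_ci(0.5), mild=_uniform_ci(0.3), moderate=_uniform_ci(0.2),
            severe=_uniform_ci(0.0), csme=_uniform_ci(0.0),
        )
        cfg = _config(horizon=3, cohort_size=1.0, initial_distribution=init)
        lt = generate_life_table(max(-np.log(1.0 - q), 1e-15), 1.0, 16)
        trace = run_cohort(cfg, tp, Arm.COMPARATOR, lt)
        expected = enumerate_paths(init.as_array(), matrices)
        np.testing.assert_allclose(trace.occupancy, expected, atol=1e-12)

    def test_monotone_in_svi_entry_probability(self, base_inputs, life_table):
        tp_lo = base_inputs.transitions
        tp_hi = dataclasses.replace(tp_lo, severe_to_svi_untreated=ParamCI(0.15, 0.15, 0.15))
        lo = run_cohort(base_inputs.config, tp_lo, Arm.COMPARATOR, life_table)
        hi = run_cohort(base_inputs.config, tp_hi, Arm.COMPARATOR, life_table)
        assert hi.person_years(HealthState.SVI) >= lo.person_years(HealthState.SVI)


class TestPersonYears:
    @pytest.fixture
    def static_trace(self):
        occ = np.zeros((26, 7))
        occ[:, HealthState.NO_DR] = 1000.0
        return CohortTrace(occ, np.zeros_like(occ), Arm.COMPARATOR, 50.0, 1000.0)

    def test_undiscounted(self, static_trace):
        assert static_trace.person_years(HealthState.NO_DR, 0.0) == pytest.approx(25_000.0)

    def test_discounted_matches_geometric_series(self, static_trace):
        expected = 1000.0 * sum(1.03 ** (-k) for k in range(25))
        got = static_trace.person_years(HealthState.NO_DR, 0.03)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(17_935.5, abs=0.5)

    def test_empty_state_is_zero(self, static_trace):
        assert static_trace.person_years(HealthState.SVI, 0.03) == 0.0


class TestTraceExport:
    def test_csv_round_trip_is_bit_exact(self, base_inputs, life_table, tmp_path):
        trace = run_cohort(base_inputs.config, base_inputs.transitions, Arm.INTERVENTION, life_table)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = CohortTrace.from_csv(path, Arm.INTERVENTION)
        np.testing.assert_array_equal(back.occupancy, trace.occupancy)
        assert back.start_age == trace.start_age
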