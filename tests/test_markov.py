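"""Markov engine: transition construction, cohort propagation, outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystcea import (
    HealthState,
    LifeTable,
    ParamSet,
    TransitionMatrix,
    accumulate_outcomes,
    build_schedule,
    build_transition_matrix,
    make_life_table,
    run_cohort,
    simulate_strategy,
)
from cystcea.markov import build_cycle_matrices
from cystcea.schedules import StrategySchedule


def _flat_table(q):
    return make_life_table("flat", {"q": q}, age_range=(40, 110))


class TestTransitionMatrix:
    def test_no_mortality_row(self, params):
        tm = build_transition_matrix(params, 60, _flat_table(0.0))
        assert tm.matrix[HealthState.ASYMPTOMATIC] == pytest.approx(
            [0.98, 0.02, 0.0]
        )

    def test_certain_death(self, params):
        tm = build_transition_matrix(params, 60, _flat_table(1.0))
        for state in (HealthState.ASYMPTOMATIC, HealthState.SYMPTOMATIC):
            assert tm.matrix[state] == pytest.approx([0.0, 0.0, 1.0])

    def test_competing_risk_product(self, params):
        # qx = 0.01: become-symptomatic applies only to survivors
        tm = build_transition_matrix(params, 60, _flat_table(0.01))
        assert tm.matrix[HealthState.ASYMPTOMATIC] == pytest.approx(
            [0.9702, 0.0198, 0.01]
        )

    def test_invasive_cycle_adds_procedural_mortality(self, params):
        tm = build_transition_matrix(
            params, 60, _flat_table(0.01), strategy_is_invasive=True
        )
        assert tm.matrix[HealthState.ASYMPTOMATIC, HealthState.DEAD] == (
            pytest.approx(0.01 + params.p_death_eusfna)
        )

    def test_rows_always_stochastic(self, params, life_table):
        for age in range(60, 90):
            tm = build_transition_matrix(params, age, life_table)
            assert tm.matrix.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0])

    def test_symptomatic_excess_mortality_when_enabled(self):
        p = ParamSet(
            include_malignant_branch=True, frac_malignant_among_symptomatic=0.15
        )
        tm = build_transition_matrix(p, 60, _flat_table(0.01))
        expected = 1 - (1 - 0.01) * (1 - 0.6 * 0.15)
        assert tm.matrix[HealthState.SYMPTOMATIC, HealthState.DEAD] == (
            pytest.approx(expected)
        )

    def test_age_outside_table_names_age(self, params):
        with pytest.raises(KeyError, match="150"):
            build_transition_matrix(params, 150, _flat_table(0.0))

    def test_dead_row_must_be_absorbing(self):
        m = np.array([[1, 0, 0], [0, 1, 0], [0.1, 0, 0.9]], dtype=float)
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(m)


def _stochastic_3x3(rows):
    m = np.array(rows, dtype=float)
    m = m / m.sum(axis=1, keepdims=True)
    m[2] = [0.0, 0.0, 1.0]
    return m


row = st.lists(
    st.floats(min_value=0.01, max_value=1.0, allow_nan=False), min_size=3, max_size=3
)


class TestRunCohort:
    def test_identity_keeps_occupancy_constant(self):
        matrices = [TransitionMatrix(np.eye(3)) for _ in range(10)]
        trace = run_cohort([1000, 0, 0], matrices)
        assert (trace.occupancy == trace.occupancy[0]).all()

    def test_half_dies_in_one_cycle(self):
        m = np.array([[0.5, 0.0, 0.5], [0, 1, 0], [0, 0, 1]], dtype=float)
        trace = run_cohort([1000, 0, 0], [TransitionMatrix(m)])
        assert trace.occupancy[1] == pytest.approx([500, 0, 500])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(rows=st.lists(row, min_size=3, max_size=3))
    def test_matches_matrix_power_closed_form(self, rows):
        """Time-homogeneous cohort propagation equals initial @ M^n."""
        m = _stochastic_3x3(rows)
        n = 10
        trace = run_cohort([1000, 0, 0], [TransitionMatrix(m)] * n)
        oracle = np.array([1000.0, 0, 0]) @ np.linalg.matrix_power(m, n)
        assert np.allclose(trace.occupancy[-1], oracle, atol=1e-10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(rows=st.lists(row, min_size=3, max_size=3))
    def test_conservation_and_death_monotonicity(self, rows):
        m = _stochastic_3x3(rows)
        trace = run_cohort([900, 100, 0], [TransitionMatrix(m)] * 10)
        assert np.allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-9)
        dead = trace.occupancy[:, HealthState.DEAD]
        assert (np.diff(dead) >= -1e-12).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="3 states"):
            run_cohort([1000, 0], [TransitionMatrix(np.eye(3))])


class TestAccumulateOutcomes:
    def _annual_ceus(self, params):
        return build_schedule("ceus", "bd_lt1cm", params)

    def test_constant_utility_no_deaths(self, flat_life_table):
        p = ParamSet(
            cohort_size=1, p_symptomatic_annual=0.0, u_aging_decrement_annual=0.0
        )
        _, qaly, _ = simulate_strategy(p, self._annual_ceus(p), flat_life_table)
        assert qaly == pytest.approx(10 * 0.78)

    def test_aging_decrement_arithmetic_series(self, flat_life_table):
        # sum_{t=1..10} (0.78 - 0.01 (t-1)) = 7.35
        p = ParamSet(cohort_size=1, p_symptomatic_annual=0.0)
        _, qaly, _ = simulate_strategy(p, self._annual_ceus(p), flat_life_table)
        assert qaly == pytest.approx(7.35)

    def test_all_dead_initial_cohort(self, params, flat_life_table):
        schedule = self._annual_ceus(params)
        matrices = build_cycle_matrices(params, flat_life_table, schedule)
        trace = run_cohort([0, 0, 1000], matrices)
        cost, qaly = accumulate_outcomes(trace, schedule, params)
        assert cost == 0.0
        assert qaly == 0.0

    def test_eus_cycles_use_invasive_utility(self, flat_life_table):
        p = ParamSet(
            cohort_size=1,
            p_symptomatic_annual=0.0,
            u_aging_decrement_annual=0.0,
            p_death_eusfna=0.0,
        )
        schedule = build_schedule("fukuoka", "bd_2_3cm", p)  # EUS every cycle
        _, qaly, _ = simulate_strategy(p, schedule, flat_life_table)
        assert qaly == pytest.approx(10 * 0.73)

    def test_symptomatic_patients_lose_decrement(self, flat_life_table):
        p = ParamSet(cohort_size=1, u_aging_decrement_annual=0.0)
        schedule = self._annual_ceus(p)
        matrices = build_cycle_matrices(p, flat_life_table, schedule)
        trace = run_cohort([0, 1, 0], matrices)  # starts symptomatic, never dies
        _, qaly = accumulate_outcomes(trace, schedule, p)
        assert qaly == pytest.approx(10 * (0.78 - 0.03))

    def test_negative_utility_clamped_with_warning(self, flat_life_table, caplog):
        p = ParamSet(
            cohort_size=1, u_aging_decrement_annual=0.09, p_symptomatic_annual=0.0
        )
        with caplog.at_level("WARNING"):
            _, qaly, _ = simulate_strategy(p, self._annual_ceus(p), flat_life_table)
        assert "clamp" in caplog.text
        # utilities floor at 0 instead of going negative
        assert qaly == pytest.approx(sum(max(0.0, 0.78 - 0.09 * t) for t in range(10)))

    def test_cost_booked_for_alive_fraction(self, params):
        # 50% die each cycle: cycle t books full cost times survivors
        half = _flat_table(0.5)
        p = ParamSet(p_symptomatic_annual=0.0)
        schedule = self._annual_ceus(p)
        matrices = build_cycle_matrices(p, half, schedule)
        trace = run_cohort([1000.0, 0, 0], matrices)
        cost, _ = accumulate_outcomes(trace, schedule, p)
        assert cost == pytest.approx(70.50 * sum(0.5**t for t in range(10)))

    def test_qaly_monotone_in_utilities_and_death(self, life_table):
        base = ParamSet()
        schedule = self._annual_ceus(base)
        _, q0, _ = simulate_strategy(base, schedule, life_table)
        _, q_up, _ = simulate_strategy(
            base.replace(u_noninvasive_surv=0.79), schedule, life_table
        )
        assert q_up > q0
        _, q_down, _ = simulate_strategy(
            base.replace(u_symptom_decrement=0.05), schedule, life_table
        )
        assert q_down <= q0
        deadlier = make_life_table(
            "gompertz_makeham", {"alpha": 4e-5}, age_range=(40, 110)
        )
        _, q_mort, _ = simulate_strategy(base, schedule, deadlier)
        assert q_mort < q0

    def test_zero_death_qalys_equal_cycles_times_utility(self, flat_life_table):
        p = ParamSet(
            cohort_size=1000,
            p_symptomatic_annual=0.0,
            u_aging_decrement_annual=0.0,
        )
        _, qaly, _ = simulate_strategy(p, self._annual_ceus(p), flat_life_table)
        assert qaly == pytest.approx(10 * 0.78, abs=1e-12)

    def test_mismatched_cycle_counts_rejected(self, params, flat_life_table):
        schedule = self._annual_ceus(params)
        matrices = build_cycle_matrices(params, flat_life_table, schedule)
        trace = run_cohort([1000, 0, 0], matrices[:5])
        short = StrategySchedule("ceus", "bd_lt1cm", schedule.exams[:4])
        with pytest.raises(ValueError, match="cycles"):
            accumulate_outcomes(trace, short, params)


class TestLifeTable:
    def test_csv_round_trip(self, tmp_path, life_table):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        assert back.ages == life_table.ages
        assert all(back.qx(a) == life_table.qx(a) for a in life_table.ages)

    def test_out_of_range_qx_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            LifeTable({60: 1.5})

    def test_coverage_check(self, life_table):
        assert life_table.covers(60, 70)
        assert not life_table.covers(60, 200)
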