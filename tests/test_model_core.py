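"""Unit tests of the weekly state equations and year stepping."""

import numpy as np
import pytest

from careflow import (
    ArrivalSeries,
    ModelParams,
    chain_years,
    init_year,
    simulate_year,
    step_diagnosed,
    step_in_treatment,
    step_interest,
    step_open_cases,
)
from careflow.model_core import WeeklyState

from reference_impl import naive_literal_year


def _naive_cfg(params: ModelParams) -> dict:
    return {
        "retention": params.retention_after_dropout,
        "f_diag": params.diagnosis_fraction,
        "f_treat": params.treatment_entry_fraction,
        "f_open": params.nondiagnosed_to_open_fraction,
        "f_closed": params.completed_to_open_fraction,
        "carryover": params.year_carryover_fraction,
        "d1": params.d1,
        "d2": params.d2,
        "d3": params.d3,
        "weeks": params.weeks_per_year,
    }


class TestScalarSteps:
    @pytest.mark.parametrize(
        "prev_open, expected",
        [(0.0, 0.0), (200.0, 100.0), (445.0, 222.5)],
    )
    def test_year_initialization_carries_half_the_open_cases(
        self, default_params, prev_open, expected
    ):
        state = init_year(prev_open, default_params)
        assert state.week_index == 0
        assert state.S_Pi == pytest.approx(expected, rel=1e-12)
        assert state.S_Pd == 0.0 and state.S_Ptr == 0.0

    @pytest.mark.parametrize(
        "nc, prev, expected",
        [(0, 0.0, 0.0), (100, 0.0, 98.0), (10, 98.0, 107.8)],
    )
    def test_interest_step_retains_98_percent_of_new_cases(
        self, default_params, nc, prev, expected
    ):
        assert step_interest(nc, prev, default_params) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "prev, lag, expected",
        [(0.0, 0.0, 0.0), (0.0, 100.0, 29.4), (50.0, 100.0, 78.4)],
    )
    def test_diagnosis_step_takes_30_percent_of_lagged_interest(
        self, default_params, prev, lag, expected
    ):
        assert step_diagnosed(prev, lag, default_params) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "prev, lag, expected",
        [(0.0, 0.0, 0.0), (0.0, 78.4, 23.52), (10.0, 100.0, 40.0)],
    )
    def test_treatment_step_takes_30_percent_of_lagged_diagnosed(
        self, default_params, prev, lag, expected
    ):
        assert step_in_treatment(prev, lag, default_params) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "current, lag, expected",
        [(0.0, 0.0, 0.0), (100.0, 0.0, 70.0), (98.0, 40.0, 88.6)],
    )
    def test_open_case_step_mixes_nondiagnosed_and_completed(
        self, default_params, current, lag, expected
    ):
        assert step_open_cases(current, lag, default_params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_inputs_are_rejected(self, default_params):
        with pytest.raises(ValueError):
            init_year(-1.0, default_params)
        with pytest.raises(ValueError):
            step_interest(-1, 0.0, default_params)
        with pytest.raises(ValueError):
            step_diagnosed(0.0, -1.0, default_params)
        with pytest.raises(ValueError):
            step_in_treatment(-0.1, 0.0, default_params)
        with pytest.raises(ValueError):
            step_open_cases(0.0, -2.0, default_params)


class TestSimulateYear:
    def test_zero_arrivals_zero_initial_gives_all_zero_trajectory(
        self, default_params
    ):
        traj = simulate_year(default_params, ArrivalSeries.zeros(52))
        for state in traj.states:
            assert state.stocks() == (0.0, 0.0, 0.0, 0.0)

    def test_matches_naive_spreadsheet_stepping(self, default_params, constant_arrivals):
        traj = simulate_year(default_params, constant_arrivals)
        rows = naive_literal_year(
            _naive_cfg(default_params), constant_arrivals.counts, prev_open=0.0
        )
        for state, row in zip(traj.states, rows):
            assert state.S_Pi == pytest.approx(row["Pi"], abs=1e-9)
            assert state.S_Pd == pytest.approx(row["Pd"], abs=1e-9)
            assert state.S_Ptr == pytest.approx(row["Ptr"], abs=1e-9)
            assert state.S_Poc == pytest.approx(row["Poc"], abs=1e-9)

    def test_doubling_arrivals_and_initial_doubles_every_stock(self, default_params):
        arr = ArrivalSeries(counts=tuple([3, 0, 7] * 17 + [5]))
        init1 = init_year(100.0, default_params)
        init2 = init_year(200.0, default_params)
        doubled = ArrivalSeries(counts=tuple(2 * c for c in arr.counts))
        t1 = simulate_year(default_params, arr, init1)
        t2 = simulate_year(default_params, doubled, init2)
        for s1, s2 in zip(t1.states, t2.states):
            assert s2.stocks() == tuple(2.0 * x for x in s1.stocks())

    def test_arrival_length_mismatch_is_rejected(self, default_params):
        with pytest.raises(ValueError, match="weeks"):
            simulate_year(default_params, ArrivalSeries.zeros(10))

    def test_initial_state_with_nonzero_diagnosed_is_rejected(self, default_params):
        bad = WeeklyState(week_index=0, S_Pi=1.0, S_Pd=1.0, S_Ptr=0.0, S_Poc=0.0)
        with pytest.raises(ValueError, match="S_Pd"):
            simulate_year(default_params, ArrivalSeries.zeros(52), bad)


class TestForwardReading:
    """The future-indexed reading of the equations, checked pointwise."""

    def test_output_satisfies_the_forward_equations(self):
        params = ModelParams(lag_direction="forward")
        arr = ArrivalSeries(counts=tuple([4, 9, 0, 2] * 13))
        traj = simulate_year(params, arr, init_year(80.0, params))
        W = params.weeks_per_year
        Pi = traj.stock_array("S_Pi")
        Pd = traj.stock_array("S_Pd")
        Ptr = traj.stock_array("S_Ptr")
        Poc = traj.stock_array("S_Poc")

        def fut(a, k):
            return a[k] if k <= W else 0.0

        rho = params.retention_after_dropout
        for n in range(1, W + 1):
            assert Pi[n] == pytest.approx(rho * arr.counts[n - 1] + Pi[n - 1], abs=1e-9)
            assert Pd[n] == pytest.approx(
                rho * (Pd[n - 1] + 0.3 * fut(Pi, n + params.d1)), abs=1e-9
            )
            assert Ptr[n] == pytest.approx(
                Ptr[n - 1] + 0.3 * fut(Pd, n + params.d2), abs=1e-9
            )
            assert Poc[n] == pytest.approx(
                0.7 * Pi[n] + 0.5 * fut(Ptr, n + params.d3), abs=1e-9
            )


class TestChainYears:
    def test_single_year_equals_simulate_year_with_zero_carryover(
        self, default_params, constant_arrivals
    ):
        chained = chain_years(default_params, [constant_arrivals])
        single = simulate_year(default_params, constant_arrivals)
        assert [s.stocks() for s in chained.states] == [
            s.stocks() for s in single.states
        ]

    def test_second_year_reinitializes_from_half_the_final_open_cases(
        self, default_params, constant_arrivals
    ):
        chained = chain_years(
            default_params, [constant_arrivals, ArrivalSeries.zeros(52)]
        )
        year1_final = chained.states[52]
        init2 = chained.year_initial_states[1]
        assert init2.S_Pi == 0.5 * year1_final.S_Poc

    def test_boundary_relation_holds_at_every_boundary(
        self, default_params, constant_arrivals
    ):
        chained = chain_years(default_params, [constant_arrivals] * 3)
        W = default_params.weeks_per_year
        for year in range(1, 3):
            prev_final = chained.states[year * W]
            assert chained.year_initial_states[year].S_Pi == (
                default_params.year_carryover_fraction * prev_final.S_Poc
            )
        assert chained.year_boundaries == [1, 53, 105]

    def test_empty_arrival_list_is_rejected(self, default_params):
        with pytest.raises(ValueError, match="at least one"):
            chain_years(default_params, [])

    def test_week_indices_are_contiguous(self, default_params, constant_arrivals):
        chained = chain_years(default_params, [constant_arrivals] * 2)
        indices = [s.week_index for s in chained.states]
        assert indices == list(range(105))


class TestTailLagPolicy:
    """Optional resolution of cross-year lags into the previous year."""

    def test_open_cases_see_previous_years_treatment_stock(self, constant_arrivals):
        params = ModelParams(carry_lags_across_years=True)
        chained = chain_years(params, [constant_arrivals] * 2)
        self_contained = chain_years(
            ModelParams(), [constant_arrivals] * 2
        )
        # year 2, local week 10 (global 62): Poc = 0.7*Pi + 0.5*Ptr(prev year, week 10)
        tail = chained.states[62]
        prev_ptr = chained.states[10].S_Ptr
        assert prev_ptr > 0.0
        assert tail.S_Poc == pytest.approx(
            0.7 * tail.S_Pi + 0.5 * prev_ptr, rel=1e-12
        )
        assert tail.S_Poc > self_contained.states[62].S_Poc
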