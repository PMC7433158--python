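"""Tests of the individual-case microsimulation and its mean-field link."""

import warnings

import numpy as np
import pytest

from careflow import (
    ArrivalSeries,
    ModelParams,
    TerminalStatus,
    expected_stage_counts,
    simulate_agents,
    summarize_cohort,
)
from careflow.model_core import _run_year_conserving
from careflow.params import ParameterRangeWarning

from reference_impl import enumerate_conserving_expectation


def _quiet_params(**kwargs) -> ModelParams:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ParameterRangeWarning)
        return ModelParams(**kwargs)


class TestMicrosimulation:
    def test_zero_arrivals_yield_no_cases_and_zero_counts(self, default_params):
        cases, counts = simulate_agents(default_params, ArrivalSeries.zeros(52), seed=0)
        assert cases == []
        for arr in counts.values():
            assert not np.any(arr)

    def test_degenerate_probabilities_give_a_fully_determined_timeline(self):
        params = _quiet_params(
            retention_after_dropout=1.0,
            diagnosis_fraction=1.0,
            treatment_entry_fraction=1.0,
        )
        arrivals = ArrivalSeries(counts=(1,) + (0,) * 51)
        cases, counts = simulate_agents(
            params, arrivals, seed=0, delay_sampling="fixed"
        )
        (case,) = cases
        assert not case.dropout_flag
        assert case.arrival_week == 1
        assert case.diagnosed_week == 1 + params.d1  # == 4
        assert case.treatment_start_week == 4 + params.d2  # == 5
        assert case.closure_week is None  # 52-week spell outlasts the year
        assert case.terminal_status is TerminalStatus.IN_TREATMENT
        assert counts["S_Pi"][1:4].tolist() == [1.0, 1.0, 1.0]
        assert counts["S_Pd"][4] == 1.0
        assert np.all(counts["S_Ptr"][5:53] == 1.0)

    def test_same_seed_reproduces_identical_output(self, default_params, intake_445):
        cases_a, counts_a = simulate_agents(default_params, intake_445, seed=123)
        cases_b, counts_b = simulate_agents(default_params, intake_445, seed=123)
        assert cases_a == cases_b
        for key in counts_a:
            np.testing.assert_array_equal(counts_a[key], counts_b[key])
        cases_c, _ = simulate_agents(default_params, intake_445, seed=124)
        assert cases_c != cases_a

    def test_every_case_gets_exactly_one_terminal_status(
        self, default_params, intake_445
    ):
        cases, _ = simulate_agents(default_params, intake_445, seed=7)
        assert len(cases) == intake_445.total
        summary = summarize_cohort(cases)
        assert sum(summary["counts"].values()) == intake_445.total
        assert sum(summary["fractions"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_attempt_mode_diagnoses_only_at_the_fixed_delay(self):
        params = _quiet_params(diagnosis_fraction=0.5)
        arrivals = ArrivalSeries.constant(5, 52)
        cases, _ = simulate_agents(
            params, arrivals, seed=3, delay_sampling="fixed",
            diagnosis_mode="single_attempt",
        )
        diagnosed = [c for c in cases if c.diagnosed_week is not None]
        assert diagnosed, "with p=0.5 some cases should be diagnosed"
        assert all(c.diagnosed_week == c.arrival_week + params.d1 for c in diagnosed)


class TestSummarize:
    def test_uniform_cohort_has_fraction_one(self, default_params):
        params = _quiet_params(
            retention_after_dropout=1.0,
            diagnosis_fraction=1.0,
            treatment_entry_fraction=1.0,
            d3=1,
        )
        arrivals = ArrivalSeries(counts=(10,) + (0,) * 51)
        cases, _ = simulate_agents(params, arrivals, seed=0, delay_sampling="fixed")
        summary = summarize_cohort(cases)
        assert summary["fractions"]["closed"] == 1.0

    def test_counts_to_fractions_arithmetic(self, default_params, intake_445):
        cases, _ = simulate_agents(default_params, intake_445, seed=11)
        summary = summarize_cohort(cases)
        total = len(cases)
        for status, count in summary["counts"].items():
            assert summary["fractions"][status] == count / total

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


class TestConservingExpectation:
    """The conserving stepper against exact pathway enumeration."""

    @pytest.mark.parametrize(
        "d1, d2, L, r1, r2",
        [(2, 1, 2, 0.3, 0.25), (3, 2, 4, 0.5, 0.5), (4, 1, 1, 1.0, 1.0)],
    )
    def test_stepper_matches_enumeration_on_small_horizon(self, d1, d2, L, r1, r2):
        weeks = 12
        params = _quiet_params(
            diagnosis_fraction=r1,
            treatment_entry_fraction=r2,
            d1=d1,
            d2=d2,
            d3=L,
            weeks_per_year=weeks,
            state_semantics="conserving",
        )
        counts = [3, 0, 2, 0, 0, 1, 0, 0, 0, 0, 0, 0]
        init_mass = 5.0
        arrays, _ = _run_year_conserving(params, counts, init_pi=init_mass)
        rho = params.retention_after_dropout
        cohorts = [(0, init_mass)] + [
            (w, rho * c) for w, c in enumerate(counts, start=1) if c
        ]
        cfg = {
            "r1": r1,
            "r2": r2,
            "f_open": params.nondiagnosed_to_open_fraction,
            "f_closed": params.completed_to_open_fraction,
            "d1": d1,
            "d2": d2,
            "L": L,
            "weeks": weeks,
        }
        expected = enumerate_conserving_expectation(cfg, cohorts)
        for name in ("S_Pi", "S_Pd", "S_Ptr", "S_Poc"):
            np.testing.assert_allclose(
                arrays[name], expected[name], rtol=0, atol=1e-12,
                err_msg=f"{name} mismatch",
            )

    def test_mass_is_conserved_through_the_year(self, default_params, intake_445):
        params = default_params.model_copy(update={"state_semantics": "conserving"})
        arrays, stress = _run_year_conserving(params, intake_445.counts, init_pi=0.0)
        # at year end every retained case is in treatment, on the open-case
        # register, or was referred externally at re-evaluation
        retained = params.retention_after_dropout * intake_445.total
        open_cases = arrays["S_Poc"][52]
        in_treatment = arrays["S_Ptr"][52]
        assert open_cases + in_treatment <= retained + 1e-9

    def test_delay_marginalized_expectation_averages_fixed_delay_runs(
        self, default_params, intake_445
    ):
        expected = expected_stage_counts(default_params, intake_445)
        fixed = expected_stage_counts(
            default_params, intake_445, marginalize_delays=False
        )
        # marginalizing over the delay sets smooths the early diagnosis ramp
        assert expected["S_Pd"][4] > 0.0
        assert fixed["S_Pd"][3] == 0.0  # fixed d1=3: nothing diagnosed before week 4
        assert expected["S_Pd"][3] > 0.0  # some cases draw d1=2
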