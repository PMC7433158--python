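"""Under-stress operating regime: capacity caps with overflow.

When incoming demand exceeds what the centre's weekly sessions can absorb,
the treatment framework shrinks and uncovered cases are served by external
services and private providers.  This module models that regime as hard
weekly caps on the evaluation (diagnosis) and treatment inflows: each
week's demanded flow is split into a served part, bounded by
``sessions_per_week * cases_per_session``, and an overflow routed to an
external-services register.  Overflowed cases leave the system by default;
an optional queueing mode carries them into the next week's demand instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .model_core import (
    ArrivalSeries,
    Trajectory,
    WeeklyState,
    _check_arrivals,
    _run_year,
    _states_from_arrays,
    init_year,
)
from .params import ModelParams

__all__ = [
    "CapacitySpec",
    "StressOutcome",
    "cap_flow",
    "simulate_year_stressed",
    "chain_years_stressed",
]


class CapacitySpec(BaseModel):
    """Weekly session capacity of the evaluation and treatment stages.

    ``None`` means unbounded.  The default evaluation capacity of 40
    sessions per week is the centre's reported all-specialist total.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    evaluation_sessions_per_week: Optional[float] = 40.0
    treatment_sessions_per_week: Optional[float] = None
    cases_per_session: float = 1.0
    queue_overflow: bool = False

    @field_validator("evaluation_sessions_per_week", "treatment_sessions_per_week")
    @classmethod
    def _cap_nonnegative(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"{info.field_name} must be nonnegative, got {v}")
        return v

    @field_validator("cases_per_session")
    @classmethod
    def _cases_positive(cls, v):
        if v <= 0:
            raise ValueError(f"cases_per_session must be positive, got {v}")
        return v

    @property
    def eval_cap(self) -> float:
        if self.evaluation_sessions_per_week is None:
            return math.inf
        return self.evaluation_sessions_per_week * self.cases_per_session

    @property
    def treat_cap(self) -> float:
        if self.treatment_sessions_per_week is None:
            return math.inf
        return self.treatment_sessions_per_week * self.cases_per_session


@dataclass
class StressOutcome:
    """Per-week served-versus-overflow accounting of a stressed run.

    Arrays are indexed like trajectory states (index 0 = week 0, all
    zero).  At every week and stage, ``served + overflow == demand``.
    """

    eval_demand: np.ndarray
    eval_served: np.ndarray
    eval_overflow: np.ndarray
    treat_demand: np.ndarray
    treat_served: np.ndarray
    treat_overflow: np.ndarray

    @property
    def total_overflow_to_external(self) -> float:
        """Total case-flow routed to external/private services; doubles as
        the count of informational notifications recorded for them."""
        return float(self.eval_overflow.sum() + self.treat_overflow.sum())


def cap_flow(demand: float, capacity: float) -> tuple[float, float]:
    """Split a demanded weekly flow into (served, overflow) under a cap."""
    if demand < 0:
        raise ValueError(f"demand must be nonnegative, got {demand}")
    if capacity < 0:
        raise ValueError(f"capacity must be nonnegative, got {capacity}")
    served = min(demand, capacity)
    return served, demand - served


def simulate_year_stressed(
    params: ModelParams,
    arrivals: ArrivalSeries,
    initial: Optional[WeeklyState] = None,
    capacity: Optional[CapacitySpec] = None,
) -> tuple[Trajectory, StressOutcome]:
    """One year with the weekly diagnosed and treatment inflows capped.

    With unbounded capacity the trajectory equals the unconstrained
    :func:`careflow.model_core.simulate_year` exactly (same arithmetic
    path), which makes the unconstrained model the no-cap limit of this one.
    """
    _check_arrivals(params, arrivals)
    if capacity is None:
        capacity = CapacitySpec()
    if initial is None:
        initial = init_year(0.0, params)
    if initial.S_Pd != 0.0 or initial.S_Ptr != 0.0:
        raise ValueError("week-0 state must have S_Pd = S_Ptr = 0")
    arrays, stress = _run_year(
        params,
        arrivals.counts,
        initial.S_Pi,
        eval_cap=capacity.eval_cap,
        treat_cap=capacity.treat_cap,
        queue_overflow=capacity.queue_overflow,
    )
    trajectory = Trajectory(
        params=params,
        arrivals=[arrivals],
        states=_states_from_arrays(arrays, 0, include_week0=True),
        year_boundaries=[1],
        year_initial_states=[initial],
    )
    return trajectory, StressOutcome(**stress)


def chain_years_stressed(
    params: ModelParams,
    yearly_arrivals: list[ArrivalSeries],
    capacity: Optional[CapacitySpec] = None,
) -> tuple[Trajectory, StressOutcome]:
    """Consecutive capacity-constrained years with annual carryover, with
    the per-week stress accounting concatenated alongside the states."""
    yearly_arrivals = list(yearly_arrivals)
    if not yearly_arrivals:
        raise ValueError("yearly_arrivals must contain at least one series")
    for series in yearly_arrivals:
        _check_arrivals(params, series)
    if capacity is None:
        capacity = CapacitySpec()

    W = params.weeks_per_year
    states: list[WeeklyState] = []
    boundaries: list[int] = []
    initials: list[WeeklyState] = []
    stress_global = {
        key: [0.0]
        for key in (
            "eval_demand",
            "eval_served",
            "eval_overflow",
            "treat_demand",
            "treat_served",
            "treat_overflow",
        )
    }
    prev_arrays = None
    prev_final_open = 0.0
    for year, series in enumerate(yearly_arrivals):
        initial = init_year(prev_final_open, params)
        arrays, stress = _run_year(
            params,
            series.counts,
            initial.S_Pi,
            prev_arrays,
            eval_cap=capacity.eval_cap,
            treat_cap=capacity.treat_cap,
            queue_overflow=capacity.queue_overflow,
        )
        initials.append(initial)
        if year == 0:
            states.extend(_states_from_arrays(arrays, 0, include_week0=True))
        else:
            states.extend(_states_from_arrays(arrays, year * W, include_week0=False))
        boundaries.append(1 + year * W)
        for key, values in stress_global.items():
            values.extend(float(x) for x in stress[key][1:])
        prev_final_open = float(arrays["S_Poc"][W])
        prev_arrays = arrays

    trajectory = Trajectory(
        params=params,
        arrivals=yearly_arrivals,
        states=states,
        year_boundaries=boundaries,
        year_initial_states=initials,
    )
    outcome = StressOutcome(
        **{key: np.asarray(values) for key, values in stress_global.items()}
    )
    return trajectory, outcome
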