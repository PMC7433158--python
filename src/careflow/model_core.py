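"""Weekly state equations and stepping kernels of the pathway system.

Four stocks are evolved over a 52-week year:

* ``S_Pi`` — population of interest (cases that entered the centre),
* ``S_Pd`` — diagnosed population,
* ``S_Ptr`` — in-treatment population,
* ``S_Poc`` — open-case population.

In the default *literal* semantics the stocks follow the printed linear
difference equations exactly (cumulative registers): with retention
``rho`` and weekly progression fractions ``f_d``/``f_t``,

.. code-block:: text

    S_Pi(0)  = carryover * S_Poc(prev year, final week)
    S_Pi(n)  = rho * NC(n) + S_Pi(n-1)
    S_Pd(n)  = rho * (S_Pd(n-1) + f_d * S_Pi(n - d1))
    S_Ptr(n) = S_Ptr(n-1) + f_t * S_Pd(n - d2)
    S_Poc(n) = f_open * S_Pi(n) + f_closed * S_Ptr(n - d3)

The delays d1, d2, d3 are interpreted as look-backs; lagged look-ups that
fall before week 0 resolve to zero (or, optionally, to the tail of the
previous year's trajectory when chaining).  The *conserving* semantics
instead moves head-counts between stage-structured compartments and is the
exact mean-field expectation of the agent microsimulation in
:mod:`careflow.agents`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "WeeklyState",
    "ArrivalSeries",
    "Trajectory",
    "init_year",
    "step_interest",
    "step_diagnosed",
    "step_in_treatment",
    "step_open_cases",
    "simulate_year",
    "chain_years",
]

_INF = math.inf


def _require_nonnegative(**values: float) -> None:
    for name, value in values.items():
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")


@dataclass(frozen=True)
class WeeklyState:
    """The four stock values at one week (week 0 = state at year start)."""

    week_index: int
    S_Pi: float
    S_Pd: float
    S_Ptr: float
    S_Poc: float

    def __post_init__(self) -> None:
        if self.week_index < 0:
            raise ValueError(f"week_index must be >= 0, got {self.week_index}")
        _require_nonnegative(
            S_Pi=self.S_Pi, S_Pd=self.S_Pd, S_Ptr=self.S_Ptr, S_Poc=self.S_Poc
        )

    def stocks(self) -> tuple[float, float, float, float]:
        return (self.S_Pi, self.S_Pd, self.S_Ptr, self.S_Poc)


@dataclass(frozen=True)
class ArrivalSeries:
    """Weekly counts of new cases, one entry per week of a year."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        for c in counts:
            if c < 0:
                raise ValueError(f"arrival counts must be nonnegative, got {c}")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @classmethod
    def constant(cls, value: int, weeks: int) -> "ArrivalSeries":
        return cls(counts=(value,) * weeks)

    @classmethod
    def zeros(cls, weeks: int) -> "ArrivalSeries":
        return cls.constant(0, weeks)


@dataclass
class Trajectory:
    """Arrivals plus weekly states over one or more chained years.

    ``states`` is one contiguous sequence: the very first entry is the
    week-0 initialization state, followed by ``weeks_per_year`` weekly
    states per simulated year (week indices are global).  Each later
    year's re-initialized week-0 state is kept in ``year_initial_states``
    (local ``week_index`` 0) so the annual-carryover relation remains
    checkable at every boundary.
    """

    params: ModelParams
    arrivals: list[ArrivalSeries]
    states: list[WeeklyState]
    year_boundaries: list[int] = field(default_factory=list)
    year_initial_states: list[WeeklyState] = field(default_factory=list)

    @property
    def n_years(self) -> int:
        return len(self.arrivals)

    @property
    def final_open_cases(self) -> float:
        return self.states[-1].S_Poc

    def stock_array(self, name: str) -> np.ndarray:
        """Full per-state array (including the week-0 entry) of one stock."""
        return np.array([getattr(s, name) for s in self.states], dtype=float)

    def weekly_frame(self) -> pd.DataFrame:
        """One row per simulated week (the week-0 init row is excluded)."""
        new_cases = [c for series in self.arrivals for c in series.counts]
        weekly = self.states[1:]
        return pd.DataFrame(
            {
                "week": [s.week_index for s in weekly],
                "new_cases": new_cases,
                "S_Pi": [s.S_Pi for s in weekly],
                "S_Pd": [s.S_Pd for s in weekly],
                "S_Ptr": [s.S_Ptr for s in weekly],
                "S_Poc": [s.S_Poc for s in weekly],
            }
        )

    def year_states(self, year: int) -> list[WeeklyState]:
        """The weekly states (weeks 1..W) of one year (0-based index)."""
        W = self.params.weeks_per_year
        start = 1 + year * W
        return self.states[start : start + W]


# ---------------------------------------------------------------------------
# The five state equations as scalar steps
# ---------------------------------------------------------------------------

def init_year(prev_year_final_open: float, params: ModelParams) -> WeeklyState:
    """Week-0 state of a new year: the carried-over share of last year's
    open cases re-enters the population of interest; all other stocks reset."""
    _require_nonnegative(prev_year_final_open=prev_year_final_open)
    return WeeklyState(
        week_index=0,
        S_Pi=params.year_carryover_fraction * prev_year_final_open,
        S_Pd=0.0,
        S_Ptr=0.0,
        S_Poc=0.0,
    )


def step_interest(NC_t: float, prev_Pi: float, params: ModelParams) -> float:
    """Population of interest: retained new arrivals accrue onto the register."""
    _require_nonnegative(NC_t=NC_t, prev_Pi=prev_Pi)
    return params.retention_after_dropout * NC_t + prev_Pi


def step_diagnosed(prev_Pd: float, lagged_Pi: float, params: ModelParams) -> float:
    """Diagnosed population: a weekly fraction of the incoming stock d1 weeks
    earlier is diagnosed; the dropout factor applies to the whole register."""
    _require_nonnegative(prev_Pd=prev_Pd, lagged_Pi=lagged_Pi)
    return params.retention_after_dropout * (
        prev_Pd + params.diagnosis_fraction * lagged_Pi
    )


def step_in_treatment(prev_Ptr: float, lagged_Pd: float, params: ModelParams) -> float:
    """In-treatment population: a weekly fraction of the diagnosed stock d2
    weeks earlier starts a treatment plan."""
    _require_nonnegative(prev_Ptr=prev_Ptr, lagged_Pd=lagged_Pd)
    return prev_Ptr + params.treatment_entry_fraction * lagged_Pd


def step_open_cases(current_Pi: float, lagged_Ptr: float, params: ModelParams) -> float:
    """Open cases: the non-diagnosed share of the incoming stock plus the
    share of treatment completers (d3 weeks after treatment start) that
    remain administratively open."""
    _require_nonnegative(current_Pi=current_Pi, lagged_Ptr=lagged_Ptr)
    return (
        params.nondiagnosed_to_open_fraction * current_Pi
        + params.completed_to_open_fraction * lagged_Ptr
    )


# ---------------------------------------------------------------------------
# Year engines
# ---------------------------------------------------------------------------

def _capped(demand: float, capacity: float) -> tuple[float, float]:
    served = demand if demand <= capacity else capacity
    return served, demand - served


def _run_year_literal(
    params: ModelParams,
    counts: Sequence[int],
    init_pi: float,
    prev: Optional[dict[str, np.ndarray]] = None,
    eval_cap: float = _INF,
    treat_cap: float = _INF,
    queue_overflow: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """One year of the literal cumulative-register equations.

    ``prev`` optionally supplies the previous year's stock arrays (local
    indices 0..W) for lagged look-ups crossing the year start; otherwise
    those look-ups resolve to zero.  Flow caps (``eval_cap``/``treat_cap``)
    apply to the weekly diagnosed and treatment inflows; with infinite caps
    the arithmetic path is identical to the unconstrained model.
    """
    W = params.weeks_per_year
    rho = params.retention_after_dropout
    f_d = params.diagnosis_fraction
    f_t = params.treatment_entry_fraction
    f_open = params.nondiagnosed_to_open_fraction
    f_closed = params.completed_to_open_fraction
    d1, d2, d3 = params.d1, params.d2, params.d3
    carry = params.carry_lags_across_years and prev is not None

    Pi = np.zeros(W + 1)
    Pd = np.zeros(W + 1)
    Ptr = np.zeros(W + 1)
    Poc = np.zeros(W + 1)
    stress = {
        key: np.zeros(W + 1)
        for key in (
            "eval_demand",
            "eval_served",
            "eval_overflow",
            "treat_demand",
            "treat_served",
            "treat_overflow",
        )
    }

    def lag(arr: np.ndarray, k: int, name: str) -> float:
        if k >= 0:
            return float(arr[k])
        if carry:
            return float(prev[name][W + k])
        return 0.0

    Pi[0] = init_pi
    Poc[0] = f_open * init_pi + f_closed * lag(Ptr, -d3, "S_Ptr")

    eval_backlog = 0.0
    treat_backlog = 0.0
    for n in range(1, W + 1):
        Pi[n] = rho * counts[n - 1] + Pi[n - 1]

        eval_demand = f_d * lag(Pi, n - d1, "S_Pi") + eval_backlog
        eval_served, eval_over = _capped(eval_demand, eval_cap)
        Pd[n] = rho * (Pd[n - 1] + eval_served)

        treat_demand = f_t * lag(Pd, n - d2, "S_Pd") + treat_backlog
        treat_served, treat_over = _capped(treat_demand, treat_cap)
        Ptr[n] = Ptr[n - 1] + treat_served

        Poc[n] = f_open * Pi[n] + f_closed * lag(Ptr, n - d3, "S_Ptr")

        if queue_overflow:
            eval_backlog, treat_backlog = eval_over, treat_over
        stress["eval_demand"][n] = eval_demand
        stress["eval_served"][n] = eval_served
        stress["eval_overflow"][n] = eval_over
        stress["treat_demand"][n] = treat_demand
        stress["treat_served"][n] = treat_served
        stress["treat_overflow"][n] = treat_over

    return {"S_Pi": Pi, "S_Pd": Pd, "S_Ptr": Ptr, "S_Poc": Poc}, stress


def _run_year_forward(
    params: ModelParams, counts: Sequence[int], init_pi: float
) -> dict[str, np.ndarray]:
    """The future-indexed reading of the printed equations, evaluated stage
    by stage (the system is feed-forward, so each stage's full-year series
    is known before the next one needs it).  Indices beyond the year's
    horizon resolve to zero."""
    W = params.weeks_per_year
    rho = params.retention_after_dropout

    Pi = np.zeros(W + 1)
    Pi[0] = init_pi
    for n in range(1, W + 1):
        Pi[n] = rho * counts[n - 1] + Pi[n - 1]

    def future(arr: np.ndarray, k: int) -> float:
        return float(arr[k]) if k <= W else 0.0

    Pd = np.zeros(W + 1)
    for n in range(1, W + 1):
        Pd[n] = rho * (Pd[n - 1] + params.diagnosis_fraction * future(Pi, n + params.d1))
    Ptr = np.zeros(W + 1)
    for n in range(1, W + 1):
        Ptr[n] = Ptr[n - 1] + params.treatment_entry_fraction * future(Pd, n + params.d2)
    Poc = np.zeros(W + 1)
    Poc[0] = params.nondiagnosed_to_open_fraction * Pi[0]
    for n in range(1, W + 1):
        Poc[n] = (
            params.nondiagnosed_to_open_fraction * Pi[n]
            + params.completed_to_open_fraction * future(Ptr, n + params.d3)
        )
    return {"S_Pi": Pi, "S_Pd": Pd, "S_Ptr": Ptr, "S_Poc": Poc}


def _run_year_conserving(
    params: ModelParams,
    counts: Sequence[int],
    init_pi: float,
    eval_cap: float = _INF,
    treat_cap: float = _INF,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """One year of conserving (head-count) semantics.

    Cases sit in stage-structured compartments: a d1-week waiting queue then
    a memoryless pool diagnosed at rate ``diagnosis_fraction`` per week; a
    d2-week queue then a pool entering treatment at rate
    ``treatment_entry_fraction``; a fixed d3-week treatment spell after
    which ``completed_to_open_fraction`` of completers join the open-case
    register.  At the final week a year-end re-evaluation moves
    ``nondiagnosed_to_open_fraction`` of the still-undiagnosed mass and all
    diagnosed-but-untreated mass to the open cases (the remainder of the
    undiagnosed mass is referred to external services).

    This stepper is the exact expectation of the agent microsimulation run
    with the same fixed delays, which is what makes it usable as the
    deterministic side of the stochastic cross-validation.
    """
    W = params.weeks_per_year
    rho = params.retention_after_dropout
    r1 = params.diagnosis_fraction
    r2 = params.treatment_entry_fraction
    d1, d2, L = params.d1, params.d2, params.d3

    wait1 = [0.0] * d1  # index = weeks since arrival
    elig1 = 0.0
    wait2 = [0.0] * d2  # index = weeks since diagnosis
    elig2 = 0.0
    intreat = [0.0] * L  # index = weeks since treatment start
    open_register = 0.0

    Pi = np.zeros(W + 1)
    Pd = np.zeros(W + 1)
    Ptr = np.zeros(W + 1)
    Poc = np.zeros(W + 1)
    stress = {
        key: np.zeros(W + 1)
        for key in (
            "eval_demand",
            "eval_served",
            "eval_overflow",
            "treat_demand",
            "treat_served",
            "treat_overflow",
        )
    }

    wait1[0] = init_pi  # carried-over cases re-open at week 0, no second dropout
    Pi[0] = init_pi

    for n in range(1, W + 1):
        # age the queues; mass completing its waiting period becomes eligible
        elig1 += wait1[-1]
        wait1 = [0.0] + wait1[:-1]
        elig2 += wait2[-1]
        wait2 = [0.0] + wait2[:-1]
        closing = intreat[-1]
        intreat = [0.0] + intreat[:-1]
        open_register += params.completed_to_open_fraction * closing

        wait1[0] += rho * counts[n - 1]

        eval_demand = r1 * elig1
        eval_served, eval_over = _capped(eval_demand, eval_cap)
        elig1 -= eval_demand  # overflow leaves for external services
        wait2[0] += eval_served

        treat_demand = r2 * elig2
        treat_served, treat_over = _capped(treat_demand, treat_cap)
        elig2 -= treat_demand
        intreat[0] += treat_served

        if n == W:
            # year-end re-evaluation
            pi_rest = sum(wait1) + elig1
            pd_rest = sum(wait2) + elig2
            open_register += params.nondiagnosed_to_open_fraction * pi_rest
            open_register += pd_rest
            pi_rest = 0.0
            pd_rest = 0.0
            Pi[n] = pi_rest
            Pd[n] = pd_rest
        else:
            Pi[n] = sum(wait1) + elig1
            Pd[n] = sum(wait2) + elig2
        Ptr[n] = sum(intreat)
        Poc[n] = open_register
        stress["eval_demand"][n] = eval_demand
        stress["eval_served"][n] = eval_served
        stress["eval_overflow"][n] = eval_over
        stress["treat_demand"][n] = treat_demand
        stress["treat_served"][n] = treat_served
        stress["treat_overflow"][n] = treat_over

    return {"S_Pi": Pi, "S_Pd": Pd, "S_Ptr": Ptr, "S_Poc": Poc}, stress


def _run_year(
    params: ModelParams,
    counts: Sequence[int],
    init_pi: float,
    prev: Optional[dict[str, np.ndarray]] = None,
    eval_cap: float = _INF,
    treat_cap: float = _INF,
    queue_overflow: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    if params.state_semantics == "conserving":
        return _run_year_conserving(params, counts, init_pi, eval_cap, treat_cap)
    if params.lag_direction == "forward":
        if math.isfinite(eval_cap) or math.isfinite(treat_cap):
            raise ValueError("capacity caps are not defined for forward lag_direction")
        arrays = _run_year_forward(params, counts, init_pi)
        W = params.weeks_per_year
        zeros = {
            key: np.zeros(W + 1)
            for key in (
                "eval_demand",
                "eval_served",
                "eval_overflow",
                "treat_demand",
                "treat_served",
                "treat_overflow",
            )
        }
        return arrays, zeros
    return _run_year_literal(
        params, counts, init_pi, prev, eval_cap, treat_cap, queue_overflow
    )


def _check_arrivals(params: ModelParams, arrivals: ArrivalSeries) -> None:
    if len(arrivals) != params.weeks_per_year:
        raise ValueError(
            f"arrival series has {len(arrivals)} weeks, expected "
            f"weeks_per_year={params.weeks_per_year}"
        )


def _states_from_arrays(
    arrays: dict[str, np.ndarray], week_offset: int, include_week0: bool
) -> list[WeeklyState]:
    start = 0 if include_week0 else 1
    return [
        WeeklyState(
            week_index=week_offset + n,
            S_Pi=float(arrays["S_Pi"][n]),
            S_Pd=float(arrays["S_Pd"][n]),
            S_Ptr=float(arrays["S_Ptr"][n]),
            S_Poc=float(arrays["S_Poc"][n]),
        )
        for n in range(start, len(arrays["S_Pi"]))
    ]


def simulate_year(
    params: ModelParams,
    arrivals: ArrivalSeries,
    initial: Optional[WeeklyState] = None,
    prev: Optional[Trajectory] = None,
) -> Trajectory:
    """Simulate one year of weekly states.

    ``initial`` defaults to a zero-carryover week-0 state.  ``prev`` may
    supply the previous year's trajectory for lagged look-ups crossing the
    year start (used only when ``params.carry_lags_across_years`` is set).
    """
    _check_arrivals(params, arrivals)
    if initial is None:
        initial = init_year(0.0, params)
    if initial.S_Pd != 0.0 or initial.S_Ptr != 0.0:
        raise ValueError("week-0 state must have S_Pd = S_Ptr = 0")
    prev_arrays = None
    if prev is not None:
        W = params.weeks_per_year
        prev_states = prev.states[-(W + 1) :]
        prev_arrays = {
            name: np.array([getattr(s, name) for s in prev_states])
            for name in ("S_Pi", "S_Pd", "S_Ptr", "S_Poc")
        }
    arrays, _ = _run_year(params, arrivals.counts, initial.S_Pi, prev_arrays)
    states = _states_from_arrays(arrays, week_offset=0, include_week0=True)
    return Trajectory(
        params=params,
        arrivals=[arrivals],
        states=states,
        year_boundaries=[1],
        year_initial_states=[initial],
    )


def chain_years(
    params: ModelParams,
    yearly_arrivals: Sequence[ArrivalSeries],
    n_years: Optional[int] = None,
) -> Trajectory:
    """Simulate consecutive years, re-initializing each new year from the
    carried-over share of the previous year's final open cases."""
    yearly_arrivals = list(yearly_arrivals)
    if not yearly_arrivals:
        raise ValueError("yearly_arrivals must contain at least one series")
    if n_years is not None and n_years != len(yearly_arrivals):
        raise ValueError(
            f"n_years={n_years} does not match {len(yearly_arrivals)} arrival series"
        )
    for series in yearly_arrivals:
        _check_arrivals(params, series)

    W = params.weeks_per_year
    states: list[WeeklyState] = []
    boundaries: list[int] = []
    initials: list[WeeklyState] = []
    prev_arrays: Optional[dict[str, np.ndarray]] = None
    prev_final_open = 0.0

    for year, series in enumerate(yearly_arrivals):
        initial = init_year(prev_final_open, params)
        arrays, _ = _run_year(params, series.counts, initial.S_Pi, prev_arrays)
        initials.append(initial)
        if year == 0:
            states.extend(_states_from_arrays(arrays, 0, include_week0=True))
        else:
            states.extend(_states_from_arrays(arrays, year * W, include_week0=False))
        boundaries.append(1 + year * W)
        prev_final_open = float(arrays["S_Poc"][W])
        prev_arrays = arrays

    return Trajectory(
        params=params,
        arrivals=yearly_arrivals,
        states=states,
        year_boundaries=boundaries,
        year_initial_states=initials,
    )
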