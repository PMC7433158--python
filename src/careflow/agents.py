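"""Individual-case stochastic microsimulation of the care pathway.

Each arriving case is simulated through the narrative pathway: intake (with
a dropout draw), a waiting period of d1 weeks to the first assessment
meeting, weekly diagnosis attempts, a d2-week wait to the treatment
decision, weekly treatment-entry attempts, a fixed-length treatment spell,
and a year-end re-evaluation.  Seed-averaged weekly stage counts converge
to the conserving deterministic trajectory, which makes this module a
brute-force oracle for the mean-field equations (and vice versa).

All draws flow from one seeded generator in arrival order, so a given
(seed, params, arrivals) triple reproduces byte-identical case lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np

from .model_core import ArrivalSeries, _run_year_conserving
from .params import ModelParams

__all__ = [
    "AgentCase",
    "TerminalStatus",
    "simulate_agents",
    "summarize_cohort",
    "expected_stage_counts",
    "DELAY_SETS",
]

# the printed transition-delay sets the microsimulation samples from
DELAY_SETS = {"d1": (2, 3, 4), "d2": (1, 2)}


class TerminalStatus(str, Enum):
    DROPPED_OUT = "dropped_out"
    OPEN_NO_TREATMENT = "open_no_treatment"
    IN_TREATMENT = "in_treatment"
    CLOSED = "closed"
    REFERRED_EXTERNAL = "referred_external"


@dataclass(frozen=True)
class AgentCase:
    """One simulated case's pathway through the centre."""

    case_id: int
    arrival_week: int
    dropout_flag: bool
    diagnosed_week: Optional[int]
    treatment_start_week: Optional[int]
    closure_week: Optional[int]
    terminal_status: TerminalStatus
    remains_open: bool = False

    def __post_init__(self) -> None:
        weeks = [
            w
            for w in (
                self.arrival_week,
                self.diagnosed_week,
                self.treatment_start_week,
                self.closure_week,
            )
            if w is not None
        ]
        if any(b < a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"case {self.case_id}: pathway weeks are out of order")


def _geometric(rng: np.random.Generator, p: float) -> int:
    """Number of weekly attempts until the first success (inf if p == 0)."""
    if p <= 0.0:
        return np.iinfo(np.int64).max
    if p >= 1.0:
        return 1
    return int(rng.geometric(p))


def simulate_agents(
    params: ModelParams,
    arrivals: ArrivalSeries,
    seed: int,
    delay_sampling: Literal["uniform", "fixed"] = "uniform",
    diagnosis_mode: Literal["weekly", "single_attempt"] = "weekly",
    treatment_duration: Literal["fixed", "uniform"] = "fixed",
) -> tuple[list[AgentCase], dict[str, np.ndarray]]:
    """Simulate every arriving case individually for one year.

    Parameters
    ----------
    delay_sampling
        ``"uniform"`` draws each case's d1/d2 uniformly from the printed
        sets {2,3,4} and {1,2}; ``"fixed"`` uses ``params.d1``/``params.d2``.
    diagnosis_mode
        ``"weekly"`` retries the diagnosis with probability
        ``diagnosis_fraction`` each week after the waiting period;
        ``"single_attempt"`` makes one Bernoulli attempt at exactly the
        waiting period's end (never-diagnosed cases stay in the incoming
        stock until the year-end re-evaluation).
    treatment_duration
        ``"fixed"`` treats for exactly d3 weeks; ``"uniform"`` draws the
        spell uniformly from 1..d3.

    Returns the case list and weekly stage head-counts (arrays of length
    ``weeks_per_year + 1``; index 0 is week 0).
    """
    if len(arrivals) != params.weeks_per_year:
        raise ValueError(
            f"arrival series has {len(arrivals)} weeks, expected "
            f"{params.weeks_per_year}"
        )
    W = params.weeks_per_year
    rho = params.retention_after_dropout
    r1 = params.diagnosis_fraction
    r2 = params.treatment_entry_fraction
    rng = np.random.default_rng(seed)

    counts = {
        name: np.zeros(W + 1, dtype=float)
        for name in ("S_Pi", "S_Pd", "S_Ptr", "S_Poc")
    }

    def occupy(name: str, first: int, last: int) -> None:
        if last >= first:
            counts[name][first : last + 1] += 1.0

    cases: list[AgentCase] = []
    case_id = 0
    for w in range(1, W + 1):
        for _ in range(arrivals.counts[w - 1]):
            case = _simulate_one(
                case_id, w, W, rho, r1, r2, params, rng,
                delay_sampling, diagnosis_mode, treatment_duration,
            )
            cases.append(case)
            case_id += 1
            if case.dropout_flag:
                continue
            t = case.diagnosed_week
            u = case.treatment_start_week
            c = case.closure_week
            # incoming stock until diagnosis (exclusive) or week W-1, after
            # which the year-end re-evaluation relocates the case
            occupy("S_Pi", w, min((t if t is not None else W) - 1, W - 1))
            if t is not None:
                occupy("S_Pd", t, min((u if u is not None else W) - 1, W - 1))
            if u is not None:
                occupy("S_Ptr", u, min((c if c is not None else W + 1) - 1, W))
            if c is not None and case.remains_open:
                occupy("S_Poc", c, W)
            if case.terminal_status is TerminalStatus.OPEN_NO_TREATMENT:
                occupy("S_Poc", W, W)
    return cases, counts


def _simulate_one(
    case_id: int,
    w: int,
    W: int,
    rho: float,
    r1: float,
    r2: float,
    params: ModelParams,
    rng: np.random.Generator,
    delay_sampling: str,
    diagnosis_mode: str,
    treatment_duration: str,
) -> AgentCase:
    if rng.random() >= rho:
        return AgentCase(
            case_id=case_id,
            arrival_week=w,
            dropout_flag=True,
            diagnosed_week=None,
            treatment_start_week=None,
            closure_week=None,
            terminal_status=TerminalStatus.DROPPED_OUT,
        )

    if delay_sampling == "uniform":
        d1 = int(rng.choice(DELAY_SETS["d1"]))
    else:
        d1 = params.d1
    if diagnosis_mode == "single_attempt":
        t = w + d1 if rng.random() < r1 else None
        if t is not None and t > W:
            t = None
    else:
        t = w + d1 + _geometric(rng, r1) - 1
    if t is None or t > W:
        # never diagnosed this year: re-evaluated at year end
        if rng.random() < params.nondiagnosed_to_open_fraction:
            status, open_flag = TerminalStatus.OPEN_NO_TREATMENT, False
        else:
            status, open_flag = TerminalStatus.REFERRED_EXTERNAL, False
        return AgentCase(
            case_id=case_id,
            arrival_week=w,
            dropout_flag=False,
            diagnosed_week=None,
            treatment_start_week=None,
            closure_week=None,
            terminal_status=status,
            remains_open=open_flag,
        )

    if delay_sampling == "uniform":
        d2 = int(rng.choice(DELAY_SETS["d2"]))
    else:
        d2 = params.d2
    u = t + d2 + _geometric(rng, r2) - 1
    if u > W:
        # diagnosed but never started treatment: an open case at year end
        return AgentCase(
            case_id=case_id,
            arrival_week=w,
            dropout_flag=False,
            diagnosed_week=t,
            treatment_start_week=None,
            closure_week=None,
            terminal_status=TerminalStatus.OPEN_NO_TREATMENT,
        )

    if treatment_duration == "uniform":
        spell = int(rng.integers(1, params.d3 + 1))
    else:
        spell = params.d3
    c = u + spell
    if c > W:
        return AgentCase(
            case_id=case_id,
            arrival_week=w,
            dropout_flag=False,
            diagnosed_week=t,
            treatment_start_week=u,
            closure_week=None,
            terminal_status=TerminalStatus.IN_TREATMENT,
        )
    remains_open = bool(rng.random() < params.completed_to_open_fraction)
    return AgentCase(
        case_id=case_id,
        arrival_week=w,
        dropout_flag=False,
        diagnosed_week=t,
        treatment_start_week=u,
        closure_week=c,
        terminal_status=TerminalStatus.CLOSED,
        remains_open=remains_open,
    )


def summarize_cohort(cases: Sequence[AgentCase]) -> dict[str, dict[str, float]]:
    """Counts and fractions of terminal statuses over a simulated cohort."""
    cases = list(cases)
    if not cases:
        raise ValueError("cannot summarize an empty cohort")
    counts = {status.value: 0 for status in TerminalStatus}
    for case in cases:
        counts[case.terminal_status.value] += 1
    total = len(cases)
    fractions = {name: count / total for name, count in counts.items()}
    return {"counts": counts, "fractions": fractions}


def expected_stage_counts(
    params: ModelParams,
    arrivals: ArrivalSeries,
    marginalize_delays: bool = True,
) -> dict[str, np.ndarray]:
    """Exact expectation of the weekly agent stage counts.

    Computed from the conserving deterministic stepper; when
    ``marginalize_delays`` is set (matching the microsimulation's default
    uniform delay sampling) the expectation averages the fixed-delay
    trajectories over the printed delay sets, which is exact because the
    expected counts are linear in the per-case pathway probabilities.
    """
    combos = (
        [(d1, d2) for d1 in DELAY_SETS["d1"] for d2 in DELAY_SETS["d2"]]
        if marginalize_delays
        else [(params.d1, params.d2)]
    )
    acc: dict[str, np.ndarray] = {}
    for d1, d2 in combos:
        p = params.model_copy(update={"d1": d1, "d2": d2})
        arrays, _ = _run_year_conserving(p, arrivals.counts, init_pi=0.0)
        for name, arr in arrays.items():
            acc[name] = acc.get(name, 0.0) + arr
    return {name: arr / len(combos) for name, arr in acc.items()}
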