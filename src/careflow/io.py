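"""Serialization of trajectories, cohorts and the stock-flow diagram."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .agents import AgentCase
from .model_core import ArrivalSeries, Trajectory
from .stress import StressOutcome

__all__ = [
    "trajectory_frame",
    "write_trajectory_csv",
    "write_trajectory_json",
    "write_arrivals_csv",
    "read_arrivals_csv",
    "write_cases_csv",
    "stock_flow_dot",
    "write_dot",
]

_FLOAT_FORMAT = "%.12g"  # >= 10 significant digits

_STRESS_COLUMNS = ("eval_served", "eval_overflow", "treat_served", "treat_overflow")


def trajectory_frame(
    trajectory: Trajectory, stress: Optional[StressOutcome] = None
) -> pd.DataFrame:
    """Weekly rows of a trajectory, with stress accounting columns when a
    capacity-constrained outcome is supplied."""
    frame = trajectory.weekly_frame()
    if stress is not None:
        for name in _STRESS_COLUMNS:
            values = getattr(stress, name)
            frame[name] = values[1:]  # index 0 is the week-0 placeholder
    return frame


def write_trajectory_csv(
    trajectory: Trajectory,
    path: str | Path,
    stress: Optional[StressOutcome] = None,
) -> None:
    trajectory_frame(trajectory, stress).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


def write_trajectory_json(
    trajectory: Trajectory,
    path: str | Path,
    stress: Optional[StressOutcome] = None,
) -> None:
    frame = trajectory_frame(trajectory, stress)
    payload = {
        "params": trajectory.params.model_dump(mode="json"),
        "year_boundaries": trajectory.year_boundaries,
        "initial_states": [
            {
                "week_index": s.week_index,
                "S_Pi": s.S_Pi,
                "S_Pd": s.S_Pd,
                "S_Ptr": s.S_Ptr,
                "S_Poc": s.S_Poc,
            }
            for s in trajectory.year_initial_states
        ],
        "weeks": frame.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_arrivals_csv(series: ArrivalSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"week": range(1, len(series) + 1), "new_cases": list(series.counts)}
    ).to_csv(path, index=False)


def read_arrivals_csv(path: str | Path) -> ArrivalSeries:
    frame = pd.read_csv(path)
    missing = {"week", "new_cases"} - set(frame.columns)
    if missing:
        raise ValueError(f"arrival CSV {path} lacks columns: {sorted(missing)}")
    frame = frame.sort_values("week")
    return ArrivalSeries(counts=tuple(int(c) for c in frame["new_cases"]))


def write_cases_csv(cases: Sequence[AgentCase], path: str | Path) -> None:
    pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "arrival_week": [c.arrival_week for c in cases],
            "terminal_status": [c.terminal_status.value for c in cases],
            "diagnosed_week": [c.diagnosed_week for c in cases],
            "treatment_start_week": [c.treatment_start_week for c in cases],
            "closure_week": [c.closure_week for c in cases],
        }
    ).to_csv(path, index=False)


def stock_flow_dot(stressed: bool = False) -> str:
    """DOT source of the stock-and-flow graph: population stocks as boxes,
    case flows as solid edges, informational links dotted.  The stressed
    variant adds the external-services sink fed by capacity overflow."""
    lines = [
        "digraph pathway {",
        "  rankdir=LR;",
        '  node [shape=box, style=rounded];',
        '  intake [shape=ellipse, label="new cases"];',
        '  P_i [label="population of\\ninterest (P_i)"];',
        '  P_d [label="diagnosed (P_d)"];',
        '  P_tr [label="in treatment (P_tr)"];',
        '  P_oc [label="open cases (P_oc)"];',
        '  dropout [shape=ellipse, label="dropout (2%)"];',
        '  intake -> P_i [label="weekly arrivals"];',
        '  P_i -> dropout;',
        '  P_i -> P_d [label="evaluation\\n(30%/wk, delay d1)"];',
        '  P_d -> P_tr [label="treatment plan\\n(30%/wk, delay d2)"];',
        '  P_tr -> P_oc [label="re-evaluation\\n(50%, delay d3)"];',
        '  P_i -> P_oc [label="not diagnosed (70%)"];',
        '  P_oc -> P_i [label="50% carryover\\n(next year)", style=dashed];',
    ]
    if stressed:
        lines += [
            '  external [shape=ellipse, label="external / private\\nservices"];',
            '  school [shape=ellipse, label="school\\n(informational)"];',
            '  P_i -> external [label="evaluation overflow", color=red];',
            '  P_d -> external [label="treatment overflow", color=red];',
            '  P_d -> school [style=dotted, label="upon parent approval"];',
        ]
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_dot(path: str | Path, stressed: bool = False) -> None:
    Path(path).write_text(stock_flow_dot(stressed))
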