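"""Orchestration of a full configured run: arrivals, simulation, reports."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .arrivals import generate_arrivals
from .config import RunConfig
from .io import (
    read_arrivals_csv,
    write_dot,
    write_trajectory_csv,
    write_trajectory_json,
)
from .model_core import ArrivalSeries, Trajectory, chain_years
from .steady_state import NoFixedPointError, solve_stationary
from .stress import StressOutcome, chain_years_stressed

__all__ = ["resolve_arrivals", "run"]

logger = logging.getLogger("careflow")


def resolve_arrivals(config: RunConfig) -> list[ArrivalSeries]:
    """One arrival series per simulated year.

    A configured CSV supplies a fixed series reused every year; otherwise
    each year gets an independent Poisson draw, with per-year generator
    seeds derived deterministically from the run seed.
    """
    if config.arrivals_csv is not None:
        series = read_arrivals_csv(config.arrivals_csv)
        if len(series) != config.model.weeks_per_year:
            raise ValueError(
                f"{config.arrivals_csv} has {len(series)} weeks, expected "
                f"{config.model.weeks_per_year}"
            )
        return [series] * config.n_years
    spec = config.arrivals
    if spec.weeks != config.model.weeks_per_year:
        raise ValueError(
            f"arrival generator is set for {spec.weeks} weeks but the model year "
            f"has {config.model.weeks_per_year}"
        )
    year_seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=config.n_years
    )
    return [generate_arrivals(spec, seed=int(s)) for s in year_seeds]


def run(
    config: RunConfig,
    output_dir: Optional[str | Path] = None,
    stressed: bool = False,
) -> dict[str, Path]:
    """Execute a configured run and write its artifacts.

    Writes the trajectory (CSV/JSON per ``output_formats``), the stock-flow
    diagram (DOT), a stationary-state report and a run log recording every
    effective parameter, and returns the paths written.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.model
    yearly = resolve_arrivals(config)
    logger.info(
        "simulating %d year(s) of %d weeks (%s semantics%s)",
        config.n_years,
        params.weeks_per_year,
        params.state_semantics,
        ", stressed" if stressed else "",
    )

    stress: Optional[StressOutcome] = None
    capacity = config.capacity
    if stressed:
        trajectory, stress = chain_years_stressed(params, yearly, capacity)
    else:
        trajectory = chain_years(params, yearly)

    artifacts: dict[str, Path] = {}
    if "csv" in config.output_formats:
        path = out / "trajectory.csv"
        write_trajectory_csv(trajectory, path, stress)
        artifacts["trajectory_csv"] = path
    if "json" in config.output_formats:
        path = out / "trajectory.json"
        write_trajectory_json(trajectory, path, stress)
        artifacts["trajectory_json"] = path
    if "dot" in config.output_formats:
        path = out / "diagram.dot"
        write_dot(path, stressed=stressed)
        artifacts["diagram_dot"] = path

    stationary_path = out / "stationary.json"
    try:
        stationary = solve_stationary(
            params, yearly[0], capacity if stressed else None
        )
        stationary_path.write_text(json.dumps(stationary.to_dict(), indent=2))
        artifacts["stationary_json"] = stationary_path
    except NoFixedPointError as exc:
        logger.warning("no stationary state: %s", exc)

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(_run_log(config, trajectory, stressed), indent=2))
    artifacts["run_log"] = log_path
    logger.info("final open cases: %.3f", trajectory.final_open_cases)
    return artifacts


def _run_log(config: RunConfig, trajectory: Trajectory, stressed: bool) -> dict:
    return {
        "careflow_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "stressed": stressed,
        "effective_config": config.model_dump(mode="json"),
        "n_states": len(trajectory.states),
        "final_open_cases": trajectory.final_open_cases,
    }
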