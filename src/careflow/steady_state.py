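"""Year-to-year stationary state of the pathway system.

With self-contained years the only cross-year coupling is the annual
carryover of open cases, so the final-week open-case count is an affine
function of the previous year's final open-case count,
``Poc' = a * Poc + b``.  The map is identified by probing the one-year
simulator (exploiting the system's linearity) rather than derived
symbolically, so it stays correct under any parameter configuration; when
probing reveals a non-affine map (capacity caps, or lags carried across
year boundaries) a damped fixed-point iteration takes over.  The fixed
point ``x* = b / (1 - a)`` is the stationary open-case level at which the
centre's yearly operation repeats itself; ``|a| < 1`` makes it stable, the
condition under which the centre continues its existence with increasing
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .model_core import ArrivalSeries, _check_arrivals, _run_year, init_year
from .params import ModelParams
from .stress import CapacitySpec

__all__ = [
    "StationaryResult",
    "NoFixedPointError",
    "NonAffineMapError",
    "annual_final_open",
    "identify_annual_map",
    "find_stationary_state",
    "solve_stationary",
]

_AFFINE_CHECK_POINT = 200.0
_ITER_DAMPING = 0.5
_ITER_TOL = 1e-9
_ITER_MAX = 10_000


class NoFixedPointError(ValueError):
    """The annual map has slope exactly 1 with a nonzero intercept."""


class NonAffineMapError(ValueError):
    """Probe runs show the annual map is not affine (e.g. active caps)."""


@dataclass(frozen=True)
class StationaryResult:
    """The identified annual map and its fixed point.

    ``a``/``b`` are the map's slope and intercept (persons), ``fixed_point``
    the stationary final-week open-case count, ``stable`` whether |a| < 1,
    and ``residual`` the defect ``|map(x*) - x*]``.  ``degenerate`` marks
    the a = 1, b = 0 case where every point is fixed.
    """

    a: float
    b: float
    fixed_point: float
    stable: bool
    residual: float
    method: str = "affine"
    iterations: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "fixed_point": self.fixed_point,
            "stable": self.stable,
            "residual": self.residual,
            "method": self.method,
            "iterations": self.iterations,
            "degenerate": self.degenerate,
        }


def annual_final_open(
    params: ModelParams,
    arrivals: ArrivalSeries,
    prev_year_final_open: float,
    capacity: Optional[CapacitySpec] = None,
) -> float:
    """Final-week open-case count of one year started from a given
    previous-year final open-case count."""
    _check_arrivals(params, arrivals)
    initial = init_year(prev_year_final_open, params)
    eval_cap = capacity.eval_cap if capacity is not None else float("inf")
    treat_cap = capacity.treat_cap if capacity is not None else float("inf")
    queue = capacity.queue_overflow if capacity is not None else False
    arrays, _ = _run_year(
        params,
        arrivals.counts,
        initial.S_Pi,
        eval_cap=eval_cap,
        treat_cap=treat_cap,
        queue_overflow=queue,
    )
    return float(arrays["S_Poc"][params.weeks_per_year])


def identify_annual_map(
    params: ModelParams,
    arrivals: ArrivalSeries,
    capacity: Optional[CapacitySpec] = None,
    check: bool = True,
) -> tuple[float, float]:
    """Identify slope and intercept of the annual open-case map by probing.

    Two probe years (carryover 0 and 1) give intercept and slope; a third
    probe validates affinity and raises :class:`NonAffineMapError` when the
    system is not affine in the carryover (active capacity caps).
    """
    b = annual_final_open(params, arrivals, 0.0, capacity)
    a = annual_final_open(params, arrivals, 1.0, capacity) - b
    if check:
        probe = annual_final_open(params, arrivals, _AFFINE_CHECK_POINT, capacity)
        predicted = a * _AFFINE_CHECK_POINT + b
        if abs(probe - predicted) > 1e-6 * max(1.0, abs(probe)):
            raise NonAffineMapError(
                f"annual map is not affine: predicted {predicted!r} at carryover "
                f"{_AFFINE_CHECK_POINT}, simulated {probe!r}"
            )
    return a, b


def find_stationary_state(a: float, b: float) -> StationaryResult:
    """Fixed point of the affine annual map ``x -> a x + b``."""
    if a == 1.0:
        if b == 0.0:
            return StationaryResult(
                a=a, b=b, fixed_point=0.0, stable=False, residual=0.0,
                degenerate=True,
            )
        raise NoFixedPointError(
            f"annual map x -> x + {b} has no fixed point (slope 1, intercept != 0)"
        )
    x_star = b / (1.0 - a)
    residual = abs(a * x_star + b - x_star)
    return StationaryResult(
        a=a, b=b, fixed_point=x_star, stable=abs(a) < 1.0, residual=residual
    )


def _iterate_fixed_point(
    year_map: Callable[[float], float],
    damping: float = _ITER_DAMPING,
    tol: float = _ITER_TOL,
    max_iter: int = _ITER_MAX,
) -> tuple[float, int]:
    x = 0.0
    for k in range(1, max_iter + 1):
        fx = year_map(x)
        if abs(fx - x) < tol:
            return x, k
        x = x + damping * (fx - x)
    raise RuntimeError(
        f"fixed-point iteration did not converge within {max_iter} iterations"
    )


def solve_stationary(
    params: ModelParams,
    arrivals: ArrivalSeries,
    capacity: Optional[CapacitySpec] = None,
) -> StationaryResult:
    """Stationary annual state: affine identification with an iterative
    fallback for configurations where the map is not affine."""
    try:
        a, b = identify_annual_map(params, arrivals, capacity)
        return find_stationary_state(a, b)
    except NonAffineMapError:
        pass

    def year_map(x: float) -> float:
        return annual_final_open(params, arrivals, x, capacity)

    x_star, iterations = _iterate_fixed_point(year_map)
    h = max(1e-3, 1e-6 * abs(x_star))
    lo = max(0.0, x_star - h)
    slope = (year_map(x_star + h) - year_map(lo)) / (x_star + h - lo)
    intercept = year_map(x_star) - slope * x_star
    return StationaryResult(
        a=slope,
        b=intercept,
        fixed_point=x_star,
        stable=abs(slope) < 1.0,
        residual=abs(year_map(x_star) - x_star),
        method="iteration",
        iterations=iterations,
    )
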