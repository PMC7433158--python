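"""Synthetic weekly arrival series.

The centre's reported intake is an annual total (445 new incidents in its
latest reference year) with no published within-year pattern, so weekly
arrivals are generated as independent Poisson counts whose means sum to
the annual total — the simplest count process consistent with new cases
arising as independent events.  Optional per-week seasonality weights
reshape the means without changing the expected annual total.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .model_core import ArrivalSeries

__all__ = ["ArrivalGenSpec", "generate_arrivals", "DEFAULT_ANNUAL_INTAKE"]

#: reported annual intake of new cases (ages 0-18) used as the default mean
DEFAULT_ANNUAL_INTAKE = 445.0


class ArrivalGenSpec(BaseModel):
    """Specification of the Poisson weekly arrival generator."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    annual_total_mean: float = DEFAULT_ANNUAL_INTAKE
    weeks: int = 52
    seasonality_weights: Optional[tuple[float, ...]] = None
    seed: int = 0

    @field_validator("annual_total_mean")
    @classmethod
    def _mean_nonnegative(cls, v):
        if v < 0:
            raise ValueError(f"annual_total_mean must be nonnegative, got {v}")
        return v

    @field_validator("weeks")
    @classmethod
    def _weeks_positive(cls, v):
        if v < 1:
            raise ValueError(f"weeks must be >= 1, got {v}")
        return v

    @model_validator(mode="after")
    def _weights_valid(self):
        w = self.seasonality_weights
        if w is not None:
            if len(w) != self.weeks:
                raise ValueError(
                    f"seasonality_weights has length {len(w)}, expected {self.weeks}"
                )
            if any(x < 0 for x in w):
                raise ValueError("seasonality_weights must be nonnegative")
            if sum(w) <= 0:
                raise ValueError("seasonality_weights must have positive sum")
        return self

    def weekly_means(self) -> np.ndarray:
        if self.seasonality_weights is None:
            return np.full(self.weeks, self.annual_total_mean / self.weeks)
        weights = np.asarray(self.seasonality_weights, dtype=float)
        return self.annual_total_mean * weights / weights.sum()


def generate_arrivals(spec: ArrivalGenSpec, seed: Optional[int] = None) -> ArrivalSeries:
    """Draw one year of weekly arrival counts.

    ``seed`` overrides ``spec.seed`` when given (convenient for replicate
    draws from a single spec).  Identical seed and spec reproduce the same
    series.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = rng.poisson(spec.weekly_means())
    return ArrivalSeries(counts=tuple(int(c) for c in counts))


def replicate_totals(spec: ArrivalGenSpec, seeds: Sequence[int]) -> np.ndarray:
    """Annual totals of independently seeded replicate years."""
    return np.array(
        [generate_arrivals(spec, seed=int(s)).total for s in seeds], dtype=float
    )
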