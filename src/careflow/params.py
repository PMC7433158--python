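"""Model parameters for the weekly patient-pathway system.

The simulator tracks four population stocks of a child and adolescent
mental-health centre — incoming cases awaiting assessment (``P_i``),
diagnosed cases (``P_d``), cases in active treatment (``P_tr``) and open
cases (``P_oc``) — stepped week by week by linear state equations with
transition delays.  :class:`ModelParams` holds every coefficient and delay
of those equations plus the switches selecting the bookkeeping semantics.
"""

from __future__ import annotations

import warnings
from typing import Literal

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = ["ModelParams", "ParameterRangeWarning"]


class ParameterRangeWarning(UserWarning):
    """A parameter left the range the service itself reports for it."""


# Ranges quoted by the service for its own operation (2-5% dropout,
# 25-30% of cases progressing per week).  Values outside these ranges are
# legal but flagged, since the point defaults come from the state equations.
_RETENTION_RANGE = (0.95, 0.98)
_WEEKLY_PROGRESSION_RANGE = (0.25, 0.30)

_D1_ALLOWED = frozenset({2, 3, 4})
_D2_ALLOWED = frozenset({1, 2})

_FRACTION_FIELDS = (
    "retention_after_dropout",
    "diagnosis_fraction",
    "treatment_entry_fraction",
    "nondiagnosed_to_open_fraction",
    "completed_to_open_fraction",
    "year_carryover_fraction",
)


class ModelParams(BaseModel):
    """Coefficients, delays and semantics of the weekly state equations.

    Parameters
    ----------
    retention_after_dropout
        Fraction of cases retained past the intake/assessment dropout
        (default 0.98, i.e. a 2% dropout rate).
    diagnosis_fraction
        Fraction of the eligible incoming stock diagnosed per week.
    treatment_entry_fraction
        Fraction of the eligible diagnosed stock entering treatment per week.
    nondiagnosed_to_open_fraction
        Fraction of the never-diagnosed population counted as open cases.
    completed_to_open_fraction
        Fraction of treatment completers that remain administratively open.
    year_carryover_fraction
        Fraction of the previous year's final open cases re-entering the
        incoming stock at the start of a new year.
    d1, d2, d3
        Transition delays in weeks: incoming -> diagnosed (allowed set
        {2, 3, 4}), diagnosed -> in-treatment ({1, 2}) and in-treatment ->
        open (1..weeks_per_year; doubles as the treatment duration).
    weeks_per_year
        Length of the simulated year in weeks (default 52).
    state_semantics
        ``"literal"`` reproduces the printed cumulative-register equations
        exactly; ``"conserving"`` decrements source stocks as cases move on,
        so stocks read as concurrent head-counts (the mean-field expectation
        of the agent microsimulation).
    lag_direction
        ``"lag"`` treats the delays as look-backs (causal, default);
        ``"forward"`` evaluates the future-indexed reading of the printed
        equations stage by stage (literal semantics only).
    carry_lags_across_years
        When chaining years, resolve lagged look-ups that fall before week 0
        into the previous year's trajectory tail instead of zero.  Off by
        default so the annual carryover is the only cross-year coupling and
        the year-to-year map stays a scalar affine map.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    retention_after_dropout: float = 0.98
    diagnosis_fraction: float = 0.30
    treatment_entry_fraction: float = 0.30
    nondiagnosed_to_open_fraction: float = 0.70
    completed_to_open_fraction: float = 0.50
    year_carryover_fraction: float = 0.50
    d1: int = 3
    d2: int = 1
    d3: int = 52
    weeks_per_year: int = 52
    state_semantics: Literal["literal", "conserving"] = "literal"
    lag_direction: Literal["lag", "forward"] = "lag"
    carry_lags_across_years: bool = False

    @field_validator(*_FRACTION_FIELDS)
    @classmethod
    def _fraction_in_unit_interval(cls, v: float, info) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must lie in [0, 1], got {v}")
        return v

    @field_validator("d1")
    @classmethod
    def _d1_allowed(cls, v: int) -> int:
        if v not in _D1_ALLOWED:
            raise ValueError(f"d1 must be one of {{2, 3, 4}}, got {v}")
        return v

    @field_validator("d2")
    @classmethod
    def _d2_allowed(cls, v: int) -> int:
        if v not in _D2_ALLOWED:
            raise ValueError(f"d2 must be one of {{1, 2}}, got {v}")
        return v

    @field_validator("weeks_per_year")
    @classmethod
    def _weeks_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"weeks_per_year must be >= 1, got {v}")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "ModelParams":
        if not 1 <= self.d3 <= self.weeks_per_year:
            raise ValueError(
                f"d3 must lie in 1..weeks_per_year ({self.weeks_per_year}), got {self.d3}"
            )
        if self.lag_direction == "forward" and self.state_semantics == "conserving":
            raise ValueError(
                "forward lag_direction is defined for literal state_semantics only"
            )
        lo, hi = _RETENTION_RANGE
        if not lo <= self.retention_after_dropout <= hi:
            warnings.warn(
                f"retention_after_dropout={self.retention_after_dropout} is outside "
                f"[{lo}, {hi}], the 2-5% dropout range the service reports",
                ParameterRangeWarning,
                stacklevel=3,
            )
        lo, hi = _WEEKLY_PROGRESSION_RANGE
        for name in ("diagnosis_fraction", "treatment_entry_fraction"):
            value = getattr(self, name)
            if not lo <= value <= hi:
                warnings.warn(
                    f"{name}={value} is outside [{lo}, {hi}], the 25-30% weekly "
                    "progression range the service reports",
                    ParameterRangeWarning,
                    stacklevel=3,
                )
        return self
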