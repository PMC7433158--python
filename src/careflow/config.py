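"""Run configuration: validated parameters for a full simulation run.

Configs are JSON or YAML files whose keys match the field names below;
unknown keys are rejected and every parameter has a documented default, so
an empty file is a valid (default) configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .arrivals import ArrivalGenSpec
from .params import ModelParams
from .stress import CapacitySpec

__all__ = ["RunConfig", "ConfigError", "load_config", "write_config"]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class RunConfig(BaseModel):
    """Everything a reproducible run needs.

    ``arrivals`` specifies the synthetic Poisson generator; ``arrivals_csv``
    may instead point to a ``week,new_cases`` CSV holding one year's series
    (reused for every simulated year).  ``capacity`` enables the
    under-stress regime for the stressed subcommands.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    model: ModelParams = ModelParams()
    capacity: Optional[CapacitySpec] = None
    arrivals: ArrivalGenSpec = ArrivalGenSpec()
    arrivals_csv: Optional[str] = None
    n_years: int = 1
    seed: int = 0
    output_dir: str = "."
    output_formats: tuple[Literal["csv", "json", "dot"], ...] = ("csv", "json")

    @field_validator("n_years")
    @classmethod
    def _years_positive(cls, v):
        if v < 1:
            raise ValueError(f"n_years must be >= 1, got {v}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON/YAML config, applying documented defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # JSON is a YAML subset, one parser suffices
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping at top level")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration in {path}:\n{exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a config back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json")))
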