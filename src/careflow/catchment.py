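"""Catchment-area demographics.

The centre serves three municipal communities of Athens (the 4th, 5th and
6th); their 2001 and 2011 census populations ship as a packaged fixture.
The adjacent Galatsi municipality is also served but shares coverage with
another centre and is excluded from the single-centre catchment total.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

__all__ = [
    "CatchmentDistrict",
    "load_districts",
    "catchment_total",
    "census_change",
]


@dataclass(frozen=True)
class CatchmentDistrict:
    """One municipal community with its two census populations."""

    name: str
    population_2001: int
    population_2011: int

    def __post_init__(self) -> None:
        if self.population_2001 < 0 or self.population_2011 < 0:
            raise ValueError(f"{self.name}: populations must be nonnegative")


def load_districts() -> list[CatchmentDistrict]:
    """The packaged district table (4th, 5th and 6th municipal communities)."""
    text = resources.files("careflow").joinpath("data/districts.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    return [
        CatchmentDistrict(
            name=row["name"],
            population_2001=int(row["population_2001"]),
            population_2011=int(row["population_2011"]),
        )
        for row in rows
    ]


def catchment_total(
    districts: Sequence[CatchmentDistrict], census_year: Literal[2001, 2011] = 2011
) -> int:
    """Total residents served, summed over districts for one census year."""
    districts = list(districts)
    if not districts:
        raise ValueError("districts list must be nonempty")
    if census_year == 2011:
        return sum(d.population_2011 for d in districts)
    if census_year == 2001:
        return sum(d.population_2001 for d in districts)
    raise ValueError(f"census_year must be 2001 or 2011, got {census_year}")


def census_change(district: CatchmentDistrict) -> tuple[int, float]:
    """Absolute and percentage population change from 2001 to 2011."""
    if district.population_2001 == 0:
        raise ZeroDivisionError(
            f"{district.name}: percent change undefined for zero 2001 population"
        )
    absolute = district.population_2011 - district.population_2001
    return absolute, 100.0 * absolute / district.population_2001
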