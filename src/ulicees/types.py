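"""Core domain types for livestock GHG and land accounting.

Unit discipline: areas are carried in kha, masses (feed, protein,
nitrogen) in kt, and emissions in Tg CO2e throughout the package;
conversions happen only at I/O boundaries.  Per-head quantities
(live weight, rations, emission factors) stay in kg/head/y.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Region(str, enum.Enum):
    """Reporting region: eastern Canada (Atlantic Provinces, Québec,
    Ontario) or western Canada (Manitoba, Saskatchewan, Alberta,
    British Columbia).  CANADA labels East+West aggregates and is
    never a primary computation region."""

    EAST = "east"
    WEST = "west"
    CANADA = "canada"

    @property
    def is_aggregate(self) -> bool:
        return self is Region.CANADA


#: The two primary regions, in reporting order.
PRIMARY_REGIONS = (Region.EAST, Region.WEST)


class Industry(str, enum.Enum):
    """Livestock industry.  ALL labels cross-industry aggregates."""

    BEEF = "beef"
    DAIRY = "dairy"
    PORK = "pork"
    POULTRY = "poultry"
    ALL = "all"

    @property
    def ruminant(self) -> bool:
        return self in (Industry.BEEF, Industry.DAIRY)


class LandClass(str, enum.Enum):
    """Land-use class of a feed crop.  Silage corn, although an annual,
    is classed as FORAGE because it fills the forage role in cattle
    diets and is grouped with forages in land summaries."""

    GRAIN = "grain"
    FORAGE = "forage"
    PASTURE = "pasture"


@dataclass(frozen=True)
class GwpSet:
    """Global warming potentials used to express CH4 and N2O in CO2e.

    Defaults (21, 310) are the second-assessment-report 100-year values
    in force for national inventories around 2001.
    """

    gwp_ch4: float = 21.0
    gwp_n2o: float = 310.0

    def __post_init__(self) -> None:
        if self.gwp_ch4 <= 1 or self.gwp_n2o <= 1:
            raise ValueError("GWPs must exceed 1 (CO2e multipliers)")


@dataclass(frozen=True)
class CropSpec:
    """One feed crop: its land class, average yield and fertilizer-N
    recommendation.

    yield_t_ha : t/ha/y, must be positive for GRAIN and FORAGE crops
        (pasture area is specified directly, not derived from yield).
    n_recommendation : kg N/ha/y recommended application rate.
    """

    name: str
    land_class: LandClass
    yield_t_ha: float = 0.0
    n_recommendation: float = 0.0

    def __post_init__(self) -> None:
        if self.land_class in (LandClass.GRAIN, LandClass.FORAGE):
            if self.yield_t_ha <= 0:
                raise ValueError(
                    f"crop {self.name!r}: yield must be > 0 for "
                    f"{self.land_class.value} crops"
                )
        if self.yield_t_ha < 0 or self.n_recommendation < 0:
            raise ValueError(f"crop {self.name!r}: negative parameter")


@dataclass(frozen=True)
class CohortSpec:
    """One age-gender class of one livestock industry in one region.

    population : head (>= 0)
    live_weight : kg/head
    diet : crop name -> kg feed/head/y (as-fed mass; dry-matter
        conversion, if needed, is the caller's responsibility)
    enteric_ef : kg CH4/head/y enteric emission factor (tier-2 style,
        supplied per cohort; for swine a weight-scaled tier-1 factor)
    manure_ch4_ef : kg CH4/head/y from manure management
    manure_n : kg N/head/y excreted in manure
    pasture_kha : grazed pasture area attributed to this cohort, kha
        (specified directly; grazing has no meaningful harvest yield)
    """

    industry: Industry
    region: Region
    label: str
    population: float
    live_weight: float
    diet: Mapping[str, float] = field(default_factory=dict)
    enteric_ef: float = 0.0
    manure_ch4_ef: float = 0.0
    manure_n: float = 0.0
    pasture_kha: float = 0.0

    def __post_init__(self) -> None:
        for name, value in (
            ("population", self.population),
            ("live_weight", self.live_weight),
            ("enteric_ef", self.enteric_ef),
            ("manure_ch4_ef", self.manure_ch4_ef),
            ("manure_n", self.manure_n),
            ("pasture_kha", self.pasture_kha),
        ):
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"cohort {self.label!r}: {name} must be >= 0")
        for crop, ration in self.diet.items():
            if ration < 0:
                raise ValueError(
                    f"cohort {self.label!r}: negative ration for {crop!r}"
                )


@dataclass(frozen=True)
class EmissionBudget:
    """Annual GHG budget of one industry-region, in Tg CO2e/y.

    ``enteric_ch4`` is the enteric share of ``ch4`` (the rest being
    manure methane), kept separate to support the enteric/non-enteric
    reporting split.

    Inventory budgets are non-negative by construction.  Difference
    budgets (net changes, which may legitimately be negative) carry
    ``signed=True``, which relaxes the sign checks.
    """

    ch4: float
    n2o: float
    fossil_co2: float
    enteric_ch4: float = 0.0
    region: Region = Region.CANADA
    industry: Industry = Industry.ALL
    signed: bool = False

    _TOL = 1e-9

    def __post_init__(self) -> None:
        for name, value in (
            ("ch4", self.ch4),
            ("n2o", self.n2o),
            ("fossil_co2", self.fossil_co2),
            ("enteric_ch4", self.enteric_ch4),
        ):
            if not math.isfinite(value):
                raise ValueError(f"budget component {name} must be finite")
            if not self.signed and value < -self._TOL:
                raise ValueError(f"budget component {name} must be >= 0")
        if not self.signed and self.enteric_ch4 > self.ch4 + self._TOL:
            raise ValueError("enteric CH4 cannot exceed total CH4")

    def total(self) -> float:
        """Total annual emissions, Tg CO2e/y."""
        return self.ch4 + self.n2o + self.fossil_co2

    @property
    def non_enteric(self) -> float:
        """Manure CH4 + N2O + fossil CO2, Tg CO2e/y."""
        return self.total() - self.enteric_ch4

    def __add__(self, other: "EmissionBudget") -> "EmissionBudget":
        if not isinstance(other, EmissionBudget):
            return NotImplemented
        region = self.region if self.region == other.region else Region.CANADA
        industry = (
            self.industry if self.industry == other.industry else Industry.ALL
        )
        return EmissionBudget(
            ch4=self.ch4 + other.ch4,
            n2o=self.n2o + other.n2o,
            fossil_co2=self.fossil_co2 + other.fossil_co2,
            enteric_ch4=self.enteric_ch4 + other.enteric_ch4,
            region=region,
            industry=industry,
            signed=self.signed or other.signed,
        )

    def scaled(self, factor: float) -> "EmissionBudget":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return EmissionBudget(
            ch4=self.ch4 * factor,
            n2o=self.n2o * factor,
            fossil_co2=self.fossil_co2 * factor,
            enteric_ch4=self.enteric_ch4 * factor,
            region=self.region,
            industry=self.industry,
            signed=self.signed,
        )

    @classmethod
    def zero(
        cls,
        region: Region = Region.CANADA,
        industry: Industry = Industry.ALL,
    ) -> "EmissionBudget":
        return cls(0.0, 0.0, 0.0, 0.0, region=region, industry=industry)


def budget_total(budget: EmissionBudget) -> float:
    """Total of a budget's three gas components, Tg CO2e/y."""
    return budget.total()


def aggregate(budgets: Iterable[EmissionBudget]) -> EmissionBudget:
    """Componentwise sum of budgets.

    Region/industry labels collapse to the aggregate labels (CANADA /
    ALL) unless every input shares the same one.  An empty iterable
    yields a zero aggregate budget.
    """
    budgets = list(budgets)
    if not budgets:
        return EmissionBudget.zero()
    out = budgets[0]
    for b in budgets[1:]:
        out = out + b
    return out
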