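"""Residual-land scenarios, soil-carbon stock change, and payback periods.

When beef land is freed by a protein reallocation, the residual forage
area ΔrA can be used in four ways:

* S1 — left under ungrazed perennial forage (no new emissions);
* S2 — reseeded to annual food/feedstock crops;
* S3 — repopulated with beef of the same herd structure (mixed
  forage + grain diet);
* S4 — repopulated with mainly grass-fed beef.

Each scenario emits at a per-ha rate on ΔrA and converts a scenario-
specific area of perennial cover to annual cropping, losing soil
organic carbon.  SOC is treated as an exhaustible stock moving
exponentially to a new equilibrium; the accounting horizon is 40
years, by which time about 60% of the stock change has occurred.  The
payback period is the number of years of net annual GHG reduction
needed to repay the 40-year soil-carbon loss; when annual emissions
increase there is nothing to pay back and the period is undefined.

Per-region, per-scenario soil-loss coefficients and residual emission
rates are calibration inputs.  :func:`default_calibration` back-derives
them from the packaged study tables; they are accounting defaults, not
independent field estimates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

from .fixtures import FixtureTables, load_fixtures
from .types import EmissionBudget, Region

__all__ = [
    "Scenario",
    "ScenarioDef",
    "SoilCarbonCoeff",
    "PaybackResult",
    "Calibration",
    "decay_fraction",
    "calibrate_decay_rate",
    "residual_scenario_emissions",
    "soil_carbon_40y_loss",
    "net_decrease",
    "payback",
    "default_calibration",
    "evaluate_scenarios",
]

#: Accounting horizon for SOC equilibration, years.
DEFAULT_BENCHMARK_YEARS = 40.0
#: Share of the total SOC stock change realized by the horizon.
DEFAULT_DECAY_FRACTION_AT_HORIZON = 0.60


class Scenario(str, enum.Enum):
    S1_PERENNIAL = "s1"
    S2_ANNUALS = "s2"
    S3_BEEF_MIXED = "s3"
    S4_BEEF_GRASS = "s4"


@dataclass(frozen=True)
class ScenarioDef:
    """One residual-land scenario for one region.

    residual_emission_rate : t CO2e/ha/y applied to ΔrA (0 for S1).
    extra_annuals_kha : feed-grain area reseeded within ΔrA to support
        repopulated cattle (S3/S4 only; 0 otherwise).
    """

    id: Scenario
    residual_emission_rate: float = 0.0
    extra_annuals_kha: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_emission_rate < 0 or self.extra_annuals_kha < 0:
            raise ValueError("scenario parameters must be >= 0")
        if self.id is Scenario.S1_PERENNIAL and (
            self.residual_emission_rate or self.extra_annuals_kha
        ):
            raise ValueError("S1 keeps perennial cover: rate and extra "
                             "annuals must both be 0")
        if self.id in (Scenario.S1_PERENNIAL, Scenario.S2_ANNUALS) \
                and self.extra_annuals_kha:
            raise ValueError(f"{self.id.value} repopulates no cattle")


@dataclass(frozen=True)
class SoilCarbonCoeff:
    """40-year SOC loss per hectare converted, t CO2e/ha."""

    region: Region
    scenario: Scenario
    loss_40y_per_ha: float

    def __post_init__(self) -> None:
        if self.loss_40y_per_ha < 0:
            raise ValueError("soil loss coefficient must be >= 0")


@dataclass(frozen=True)
class PaybackResult:
    """Payback evaluation of one scenario in one region.

    ``payback_years`` is None (rendered "-") when the annual change is
    not a decrease: with no emission savings the soil-carbon debt is
    never repaid.
    """

    region: Region
    scenario: Scenario
    soil_loss_40y: float
    annual_decrease: float
    benchmark_years: float = DEFAULT_BENCHMARK_YEARS

    @property
    def payback_years(self) -> Optional[float]:
        if self.annual_decrease > 0:
            return self.soil_loss_40y / self.annual_decrease
        return None

    @property
    def ratio_to_benchmark(self) -> Optional[float]:
        p = self.payback_years
        return None if p is None else p / self.benchmark_years

    def render_payback(self, digits: int = 1) -> str:
        p = self.payback_years
        return "-" if p is None else f"{p:.{digits}f}"


# -- soil carbon decay --------------------------------------------------


def calibrate_decay_rate(
    horizon: float = DEFAULT_BENCHMARK_YEARS,
    fraction_at_horizon: float = DEFAULT_DECAY_FRACTION_AT_HORIZON,
) -> float:
    """Exponential rate k (1/y) such that the stock change reaches
    ``fraction_at_horizon`` of its asymptote at ``horizon`` years."""
    if not 0 < fraction_at_horizon < 1:
        raise ValueError("fraction must be in (0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    return -math.log(1.0 - fraction_at_horizon) / horizon


def decay_fraction(t: float, k: Optional[float] = None) -> float:
    """Fraction of the SOC stock change realized after t years:
    1 − exp(−k t).  The default k is calibrated so the fraction at 40
    years is exactly 0.60."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if k is None:
        k = calibrate_decay_rate()
    elif k <= 0:
        raise ValueError("k must be > 0")
    return 1.0 - math.exp(-k * t)


# -- scenario accounting ------------------------------------------------


def residual_scenario_emissions(delta_r_kha: float, sdef: ScenarioDef) -> float:
    """Annual GHG emissions from ΔrA under a scenario, Tg CO2e/y.

    The repopulated-cattle scenarios fold their whole-system emissions
    (animals plus feed annuals) into the per-ha rate, so the rate times
    ΔrA is the complete scenario term.  S1 is exactly zero.
    """
    if delta_r_kha < 0:
        raise ValueError("delta_r must be >= 0")
    if sdef.id is Scenario.S1_PERENNIAL:
        return 0.0
    # kha × t/ha = kt; → Tg
    return delta_r_kha * sdef.residual_emission_rate / 1e3


def soil_carbon_40y_loss(
    converted_area_kha: float, coeff: SoilCarbonCoeff
) -> float:
    """40-year soil carbon loss on the converted area, Tg CO2e.

    The converted area is ΔcA for S1, ΔcA + ΔrA for S2, and ΔcA plus
    the scenario's reseeded feed-grain annuals for S3/S4.
    """
    if converted_area_kha < 0:
        raise ValueError("converted area must be >= 0")
    return converted_area_kha * coeff.loss_40y_per_ha / 1e3


def converted_area_kha(
    scenario: Scenario,
    delta_c: float,
    delta_r: float,
    extra_annuals: float = 0.0,
) -> float:
    """Perennial area converted to annual cover under a scenario, kha."""
    if scenario is Scenario.S1_PERENNIAL:
        return delta_c
    if scenario is Scenario.S2_ANNUALS:
        return delta_c + delta_r
    return delta_c + extra_annuals


def net_decrease(base: EmissionBudget, scenario_emissions: float) -> float:
    """Net decrease in annual emissions under a scenario, Tg CO2e/y:
    the reallocation's net saving minus the scenario's own emissions.
    Negative values mean annual emissions increase."""
    return base.total() - scenario_emissions


def payback(
    soil_loss_40y: float,
    annual_decrease: float,
    benchmark: float = DEFAULT_BENCHMARK_YEARS,
    region: Region = Region.CANADA,
    scenario: Scenario = Scenario.S1_PERENNIAL,
) -> PaybackResult:
    """Payback period of a soil-carbon debt against an annual saving."""
    if soil_loss_40y < 0:
        raise ValueError("soil loss must be >= 0")
    return PaybackResult(
        region=region, scenario=scenario,
        soil_loss_40y=soil_loss_40y, annual_decrease=annual_decrease,
        benchmark_years=benchmark,
    )


# -- calibration from the packaged study tables -------------------------


@dataclass(frozen=True)
class Calibration:
    """Per-region, per-scenario accounting coefficients.

    scenario_defs : residual emission rates (t CO2e/ha/y on ΔrA) and
        reseeded-annuals areas.
    soil_coeffs : 40-year SOC loss per converted hectare (t CO2e/ha).
    """

    scenario_defs: Mapping[Tuple[Region, Scenario], ScenarioDef]
    soil_coeffs: Mapping[Tuple[Region, Scenario], SoilCarbonCoeff]


def default_calibration(
    tables: Optional[FixtureTables] = None,
) -> Calibration:
    """Back-derive scenario rates and soil coefficients from the
    packaged study tables.

    The residual rate is the printed scenario emission divided by ΔrA;
    the soil coefficient is the printed 40-year loss divided by the
    scenario's converted area.  These reproduce the study's accounting
    by construction and are defaults, not independent estimates.
    """
    tables = tables if tables is not None else load_fixtures()
    scenario_defs: Dict[Tuple[Region, Scenario], ScenarioDef] = {}
    soil_coeffs: Dict[Tuple[Region, Scenario], SoilCarbonCoeff] = {}
    for region in (Region.EAST, Region.WEST):
        delta_c = tables.area_change(region, "delta_c")
        delta_r = tables.area_change(region, "delta_r")
        extras = {
            Scenario.S1_PERENNIAL: 0.0,
            Scenario.S2_ANNUALS: 0.0,
            Scenario.S3_BEEF_MIXED: tables.area_change(region, "annuals_s3"),
            Scenario.S4_BEEF_GRASS: tables.area_change(region, "annuals_s4"),
        }
        for scenario in Scenario:
            emis = tables.scenario_emission(region, scenario.value)
            rate = 0.0 if scenario is Scenario.S1_PERENNIAL \
                else emis * 1e3 / delta_r  # Tg/kha → t/ha
            scenario_defs[(region, scenario)] = ScenarioDef(
                id=scenario,
                residual_emission_rate=rate,
                extra_annuals_kha=extras[scenario],
            )
            area = converted_area_kha(
                scenario, delta_c, delta_r, extras[scenario]
            )
            loss = tables.soil_loss(region, scenario.value)
            soil_coeffs[(region, scenario)] = SoilCarbonCoeff(
                region=region, scenario=scenario,
                loss_40y_per_ha=loss * 1e3 / area,  # Tg/kha → t/ha
            )
    return Calibration(scenario_defs=scenario_defs, soil_coeffs=soil_coeffs)


def evaluate_scenarios(
    net_by_region: Mapping[Region, EmissionBudget],
    areas_by_region: Mapping[Region, Mapping[str, float]],
    calibration: Calibration,
    benchmark: float = DEFAULT_BENCHMARK_YEARS,
) -> Dict[Tuple[Region, Scenario], PaybackResult]:
    """Full scenario evaluation for the primary regions plus their
    Canada aggregate.

    ``net_by_region`` holds each region's net annual reallocation
    saving; ``areas_by_region`` maps region → {'delta_c': …,
    'delta_r': …} in kha.  Canada rows are East+West sums; the Canada
    payback is the ratio of the summed losses to the summed decreases.
    """
    results: Dict[Tuple[Region, Scenario], PaybackResult] = {}
    for scenario in Scenario:
        total_loss = total_decrease = 0.0
        for region in (Region.EAST, Region.WEST):
            sdef = calibration.scenario_defs[(region, scenario)]
            coeff = calibration.soil_coeffs[(region, scenario)]
            areas = areas_by_region[region]
            emis = residual_scenario_emissions(areas["delta_r"], sdef)
            area = converted_area_kha(
                scenario, areas["delta_c"], areas["delta_r"],
                sdef.extra_annuals_kha,
            )
            loss = soil_carbon_40y_loss(area, coeff)
            decrease = net_decrease(net_by_region[region], emis)
            results[(region, scenario)] = PaybackResult(
                region=region, scenario=scenario,
                soil_loss_40y=loss, annual_decrease=decrease,
                benchmark_years=benchmark,
            )
            total_loss += loss
            total_decrease += decrease
        results[(Region.CANADA, scenario)] = PaybackResult(
            region=Region.CANADA, scenario=scenario,
            soil_loss_40y=total_loss, annual_decrease=total_decrease,
            benchmark_years=benchmark,
        )
    return results
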