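"""Annual GHG budget assembly for one industry-region.

Three gases are accounted for:

* CH4 — enteric fermentation (tier-2-style per-cohort emission factors
  for ruminants; weight-corrected tier-1 factors for swine) and manure
  management, both as EF × population.
* N2O — from nitrogen applied on the crop complex, split into an
  organic pathway (manure N) and a synthetic pathway (recommended N
  minus organic N, adjusted to regional fertilizer sales), each with
  its own emission factor in kg N2O-N per kg N.
* fossil CO2 — per-hectare energy coefficients (fieldwork, transport,
  heating/electricity, machinery and fertilizer manufacture) applied
  to the complex area by land class.

All pathways are linear in population and area, so a whole inventory
scales proportionally with herd size — the property the protein
reallocation study exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

from .lcc import CropComplex, land_class_summary
from .types import (
    CohortSpec,
    CropSpec,
    EmissionBudget,
    GwpSet,
    Industry,
    LandClass,
    Region,
)

#: N2O-N → N2O molecular mass ratio.
N2O_PER_N = 44.0 / 28.0

#: Default emission factors, kg N2O-N per kg N applied.  Placeholder
#: magnitudes in the range of temperate-cropland inventory values; they
#: are configuration inputs, not authoritative regional estimates.
DEFAULT_EF_ORGANIC = 0.0125
DEFAULT_EF_SYNTHETIC = 0.0125


@dataclass(frozen=True)
class NitrogenBalance:
    """Nitrogen applied on a crop complex, kt N/y.

    synthetic_n = max(0, recommended_n − organic_n) × sales_adjustment,
    the sales adjustment reconciling recommendation-based totals with
    fertilizer actually sold in the region (1.0 = no adjustment).
    """

    organic_n: float
    recommended_n: float
    sales_adjustment: float = 1.0

    def __post_init__(self) -> None:
        if min(self.organic_n, self.recommended_n) < 0:
            raise ValueError("nitrogen pools must be >= 0")
        if self.sales_adjustment < 0:
            raise ValueError("sales adjustment must be >= 0")

    @property
    def synthetic_n(self) -> float:
        return max(0.0, self.recommended_n - self.organic_n) \
            * self.sales_adjustment


@dataclass(frozen=True)
class EnergyCoefficients:
    """Fossil-energy CO2 rates by land class, t CO2e/ha/y, split into
    the four accounted components."""

    fieldwork: Mapping[LandClass, float] = field(default_factory=dict)
    transport: Mapping[LandClass, float] = field(default_factory=dict)
    heating_electricity: Mapping[LandClass, float] = field(default_factory=dict)
    manufacture: Mapping[LandClass, float] = field(default_factory=dict)

    def total_rate(self, land_class: LandClass) -> float:
        """Summed per-ha rate for one land class; KeyError naming the
        class if no component covers it."""
        parts = [self.fieldwork, self.transport,
                 self.heating_electricity, self.manufacture]
        if not any(land_class in p for p in parts):
            raise KeyError(
                f"no energy coefficient for land class {land_class.value!r}"
            )
        return sum(p.get(land_class, 0.0) for p in parts)


def swine_enteric_ef(
    base_ef: float, weight: float, reference_weight: float,
    exponent: float = 1.0,
) -> float:
    """Weight-corrected tier-1 enteric factor for hogs, kg CH4/head/y.

    Scales the default factor by (weight / reference_weight)**exponent;
    the default exponent 1 is plain linear scaling.
    """
    if reference_weight <= 0:
        raise ValueError("reference weight must be > 0")
    if weight < 0:
        raise ValueError("weight must be >= 0")
    return base_ef * (weight / reference_weight) ** exponent


def enteric_ch4(
    cohorts: Sequence[CohortSpec], gwp: GwpSet = GwpSet()
) -> float:
    """Enteric methane over cohorts, Tg CO2e/y.

    Each cohort carries its own enteric factor (kg CH4/head/y); for
    swine the factor is expected to be weight-corrected via
    :func:`swine_enteric_ef` before being stored on the cohort.
    """
    # head × kg/head/y = kg CH4/y; 1 Tg = 1e9 kg
    return sum(c.population * c.enteric_ef for c in cohorts) \
        * gwp.gwp_ch4 / 1e9


def manure_ch4(
    cohorts: Sequence[CohortSpec], gwp: GwpSet = GwpSet()
) -> float:
    """Manure-management methane over cohorts, Tg CO2e/y."""
    return sum(c.population * c.manure_ch4_ef for c in cohorts) \
        * gwp.gwp_ch4 / 1e9


def nitrogen_balance(
    cohorts: Sequence[CohortSpec],
    lcc: CropComplex,
    crops: Iterable[CropSpec],
    sales_adjustment: float = 1.0,
) -> NitrogenBalance:
    """Organic and recommended nitrogen on the complex, kt N/y.

    organic_n integrates manure N over populations; recommended_n
    integrates crop-specific recommendations over complex areas.
    """
    registry = {c.name: c for c in crops}
    organic = sum(c.population * c.manure_n for c in cohorts) / 1e6  # kg→kt
    recommended = 0.0
    for crop, area_kha in lcc.areas.items():
        if area_kha <= 0:
            continue
        if crop not in registry:
            raise KeyError(f"no nitrogen recommendation for crop {crop!r}")
        # kha × kg/ha = t; 1 kt = 1e3 t
        recommended += area_kha * registry[crop].n_recommendation / 1e3
    return NitrogenBalance(organic_n=organic, recommended_n=recommended,
                           sales_adjustment=sales_adjustment)


def n2o_emissions(
    nb: NitrogenBalance,
    ef_organic: float = DEFAULT_EF_ORGANIC,
    ef_synthetic: float = DEFAULT_EF_SYNTHETIC,
    gwp: GwpSet = GwpSet(),
) -> float:
    """N2O from applied nitrogen, Tg CO2e/y.

    (organic_n × ef_organic + synthetic_n × ef_synthetic) kt N2O-N,
    converted to N2O by 44/28 and to CO2e by the N2O GWP.
    """
    for name, ef in (("organic", ef_organic), ("synthetic", ef_synthetic)):
        if not 0 < ef < 1:
            raise ValueError(f"{name} N2O emission factor must be in (0, 1)")
    n2o_n_kt = nb.organic_n * ef_organic + nb.synthetic_n * ef_synthetic
    return n2o_n_kt * N2O_PER_N * gwp.gwp_n2o / 1e3  # kt → Tg


def fossil_co2(
    lcc: CropComplex,
    coeffs: EnergyCoefficients,
    crops: Iterable[CropSpec],
) -> float:
    """Fossil CO2 from farm energy over the complex, Tg CO2e/y.

    Applies the summed per-ha rate of each land class to the class's
    total area (harvested crops grouped by registry land class, plus
    grazed pasture).
    """
    summary = land_class_summary(lcc, crops)
    total_kt = 0.0
    for land_class, area_kha in summary.items():
        if area_kha <= 0:
            continue
        # kha × t/ha = kt
        total_kt += area_kha * coeffs.total_rate(land_class)
    return total_kt / 1e3  # kt → Tg


def assemble_budget(
    enteric: float,
    manure: float,
    n2o: float,
    fossil: float,
    region: Region,
    industry: Industry,
) -> EmissionBudget:
    """Combine the four computed gas terms (Tg CO2e/y) into a budget,
    keeping the enteric share of CH4 separate from manure methane."""
    for name, v in (("enteric", enteric), ("manure", manure),
                    ("n2o", n2o), ("fossil", fossil)):
        if v < 0:
            raise ValueError(f"negative {name} component")
    return EmissionBudget(
        ch4=enteric + manure,
        n2o=n2o,
        fossil_co2=fossil,
        enteric_ch4=enteric,
        region=region,
        industry=industry,
    )


def budget_from_inventory(
    cohorts: Sequence[CohortSpec],
    lcc: CropComplex,
    crops: Iterable[CropSpec],
    coeffs: EnergyCoefficients,
    gwp: GwpSet = GwpSet(),
    ef_organic: float = DEFAULT_EF_ORGANIC,
    ef_synthetic: float = DEFAULT_EF_SYNTHETIC,
    sales_adjustment: float = 1.0,
) -> EmissionBudget:
    """Full bottom-up budget for one industry-region."""
    crops = list(crops)
    nb = nitrogen_balance(cohorts, lcc, crops, sales_adjustment)
    return assemble_budget(
        enteric=enteric_ch4(cohorts, gwp),
        manure=manure_ch4(cohorts, gwp),
        n2o=n2o_emissions(nb, ef_organic, ef_synthetic, gwp),
        fossil=fossil_co2(lcc, coeffs, crops),
        region=cohorts[0].region,
        industry=cohorts[0].industry,
    )
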