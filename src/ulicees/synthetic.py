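"""Synthetic inventories with known ground truth.

The generator builds random but realistic cohort/diet/yield/coefficient
tables for one region and computes the expected crop complex and
emission budget with a deliberately naive, self-contained loop over
head counts and hectares (base units throughout, converted once at the
end).  That oracle shares no code with the accounting engine, so
engine-vs-truth equality is a genuine cross-check.

Distributions are pragmatic ranges — populations log-uniform between
1e2 and 1e6 head, rations and yields in ordinary agronomic ranges —
not fitted to any census; synthetic cases must never be mistaken for
survey data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .emissions import EnergyCoefficients
from .lcc import CropComplex
from .types import (
    CohortSpec,
    CropSpec,
    EmissionBudget,
    GwpSet,
    Industry,
    LandClass,
    Region,
)

__all__ = ["SyntheticCase", "RedistributionCase",
           "generate_case", "generate_redistribution_case"]

_GRAIN_CROPS = ("barley", "feed_wheat", "grain_corn", "oats", "pulses")
_FORAGE_CROPS = ("hay", "alfalfa", "silage_corn", "grass_silage")

#: kg protein per kg live weight marketed, per industry (plausible
#: carcass/protein conversion magnitudes; configuration, not survey data).
_PROTEIN_FACTORS = {
    Industry.BEEF: 0.13,
    Industry.DAIRY: 0.10,
    Industry.PORK: 0.15,
    Industry.POULTRY: 0.17,
}


@dataclass(frozen=True)
class SyntheticCase:
    """One generated single-region inventory plus its oracle truth."""

    seed: int
    region: Region
    cohorts: Tuple[CohortSpec, ...]
    crops: Tuple[CropSpec, ...]
    energy: EnergyCoefficients
    gwp: GwpSet
    ef_organic: float
    ef_synthetic: float
    sales_adjustment: float
    #: industry → expected complex, computed by the naive oracle
    truth_complexes: Mapping[Industry, CropComplex] = field(default_factory=dict)
    #: industry → expected budget, computed by the naive oracle
    truth_budgets: Mapping[Industry, EmissionBudget] = field(default_factory=dict)

    @property
    def truth_total(self) -> EmissionBudget:
        out = EmissionBudget.zero(region=self.region)
        for b in self.truth_budgets.values():
            out = out + b
        return out

    def cohorts_of(self, industry: Industry) -> List[CohortSpec]:
        return [c for c in self.cohorts if c.industry == industry]


@dataclass(frozen=True)
class RedistributionCase:
    """Paired before/after inventories for a protein reallocation.

    The after-case is built by scaling the beef herd by (1 − fraction)
    and the pork herd by the protein-conserving inflation factor, so
    protein conservation and the area identities hold by construction.
    The truth area terms are computed by the naive oracle on both
    phases.
    """

    fraction: float
    before: SyntheticCase
    after: SyntheticCase
    truth_a_p: float
    truth_a_g: float
    truth_a_f: float

    @property
    def truth_delta_c(self) -> float:
        return self.truth_a_p - self.truth_a_g

    @property
    def truth_delta_r(self) -> float:
        return self.truth_a_f - self.truth_delta_c

    def protein(self, case: SyntheticCase, industry: Industry) -> float:
        """Annual protein supply of one herd, kt (live weight ×
        conversion factor, integrated over cohorts)."""
        kg = sum(
            c.population * c.live_weight * _PROTEIN_FACTORS[c.industry]
            for c in case.cohorts if c.industry == industry
        )
        return kg / 1e6


# -- naive oracle (kept in base units: head, kg, ha) --------------------


def _naive_complex(
    cohorts: Sequence[CohortSpec], registry: Mapping[str, CropSpec]
) -> Tuple[Dict[str, float], float]:
    """(areas in kha, pasture kha) via an explicit head-by-head loop."""
    areas_ha: Dict[str, float] = {}
    pasture_kha = 0.0
    for c in cohorts:
        for crop, ration_kg in c.diet.items():
            feed_t = c.population * ration_kg / 1000.0
            areas_ha[crop] = areas_ha.get(crop, 0.0) \
                + feed_t / registry[crop].yield_t_ha
        pasture_kha += c.pasture_kha
    return {k: v / 1000.0 for k, v in areas_ha.items()}, pasture_kha


def _naive_budget(
    cohorts: Sequence[CohortSpec],
    areas_kha: Mapping[str, float],
    pasture_kha: float,
    registry: Mapping[str, CropSpec],
    energy: EnergyCoefficients,
    gwp: GwpSet,
    ef_organic: float,
    ef_synthetic: float,
    sales_adjustment: float,
    region: Region,
    industry: Industry,
) -> EmissionBudget:
    enteric_kg = sum(c.population * c.enteric_ef for c in cohorts)
    manure_kg = sum(c.population * c.manure_ch4_ef for c in cohorts)
    organic_kg = sum(c.population * c.manure_n for c in cohorts)
    recommended_kg = sum(
        area * 1000.0 * registry[crop].n_recommendation
        for crop, area in areas_kha.items()
    )
    synthetic_kg = max(0.0, recommended_kg - organic_kg) * sales_adjustment
    n2o_kg = (organic_kg * ef_organic + synthetic_kg * ef_synthetic) \
        * (44.0 / 28.0)
    fossil_t = 0.0
    by_class: Dict[LandClass, float] = {cls: 0.0 for cls in LandClass}
    for crop, area in areas_kha.items():
        by_class[registry[crop].land_class] += area
    by_class[LandClass.PASTURE] += pasture_kha
    for cls, area in by_class.items():
        if area > 0:
            fossil_t += area * 1000.0 * energy.total_rate(cls)
    return EmissionBudget(
        ch4=(enteric_kg + manure_kg) * gwp.gwp_ch4 / 1e9,
        n2o=n2o_kg * gwp.gwp_n2o / 1e9,
        fossil_co2=fossil_t / 1e6,
        enteric_ch4=enteric_kg * gwp.gwp_ch4 / 1e9,
        region=region,
        industry=industry,
    )


# -- generators ---------------------------------------------------------


def _make_crops(rng: np.random.Generator) -> Tuple[CropSpec, ...]:
    crops = []
    for name in _GRAIN_CROPS:
        crops.append(CropSpec(
            name=name, land_class=LandClass.GRAIN,
            yield_t_ha=float(rng.uniform(2.0, 8.0)),
            n_recommendation=float(rng.uniform(40.0, 140.0)),
        ))
    for name in _FORAGE_CROPS:
        crops.append(CropSpec(
            name=name, land_class=LandClass.FORAGE,
            yield_t_ha=float(rng.uniform(3.0, 12.0)),
            n_recommendation=float(rng.uniform(0.0, 60.0)),
        ))
    crops.append(CropSpec(name="pasture", land_class=LandClass.PASTURE,
                          yield_t_ha=0.0, n_recommendation=0.0))
    return tuple(crops)


def _make_energy(rng: np.random.Generator) -> EnergyCoefficients:
    def rates(scale: float) -> Dict[LandClass, float]:
        return {
            LandClass.GRAIN: float(rng.uniform(0.05, 0.4)) * scale,
            LandClass.FORAGE: float(rng.uniform(0.03, 0.25)) * scale,
            LandClass.PASTURE: float(rng.uniform(0.0, 0.05)) * scale,
        }

    return EnergyCoefficients(
        fieldwork=rates(1.0), transport=rates(0.4),
        heating_electricity=rates(0.3), manufacture=rates(0.5),
    )


_WEIGHT_RANGES = {
    Industry.BEEF: (250.0, 700.0),
    Industry.DAIRY: (400.0, 680.0),
    Industry.PORK: (20.0, 135.0),
    Industry.POULTRY: (1.0, 4.0),
}

_ENTERIC_EF_RANGES = {  # kg CH4/head/y
    Industry.BEEF: (40.0, 90.0),
    Industry.DAIRY: (70.0, 130.0),
    Industry.PORK: (1.0, 2.0),
    Industry.POULTRY: (0.0, 0.0),
}


def _make_cohort(
    rng: np.random.Generator,
    industry: Industry,
    region: Region,
    label: str,
    crops: Sequence[CropSpec],
    population: Optional[float] = None,
    forage_boost: float = 1.0,
) -> CohortSpec:
    grain_names = [c.name for c in crops if c.land_class is LandClass.GRAIN]
    forage_names = [c.name for c in crops if c.land_class is LandClass.FORAGE]
    n_crops = int(rng.integers(2, 7))
    if industry.ruminant:
        n_forage = max(1, n_crops // 2)
        picks = list(rng.choice(forage_names, size=min(n_forage, len(forage_names)), replace=False))
        picks += list(rng.choice(grain_names, size=min(n_crops - len(picks), len(grain_names)), replace=False))
    else:
        picks = list(rng.choice(grain_names, size=min(n_crops, len(grain_names)), replace=False))
    lw_lo, lw_hi = _WEIGHT_RANGES[industry]
    live_weight = float(rng.uniform(lw_lo, lw_hi))
    # annual intake roughly 15–25× live weight for ruminants, 8–12× for
    # monogastrics; split across picked crops
    intake = live_weight * (
        float(rng.uniform(15.0, 25.0)) if industry.ruminant
        else float(rng.uniform(8.0, 12.0))
    )
    shares = rng.dirichlet(np.ones(len(picks)))
    diet = {}
    for crop, share in zip(picks, shares):
        ration = float(intake * share)
        if industry.ruminant and crop in forage_names:
            ration *= forage_boost
        diet[crop] = ration
    ef_lo, ef_hi = _ENTERIC_EF_RANGES[industry]
    if population is None:
        population = float(10 ** rng.uniform(2.0, 6.0))
    return CohortSpec(
        industry=industry, region=region, label=label,
        population=population, live_weight=live_weight, diet=diet,
        enteric_ef=float(rng.uniform(ef_lo, ef_hi)),
        manure_ch4_ef=float(rng.uniform(0.5, 25.0)),
        manure_n=float(rng.uniform(5.0, 100.0)),
        pasture_kha=float(rng.uniform(0.0, 50.0)) if industry is Industry.BEEF
        else 0.0,
    )


def generate_case(
    seed: int,
    n_cohorts: int = 6,
    industry_mix: Optional[Mapping[Industry, float]] = None,
    region: Region = Region.WEST,
) -> SyntheticCase:
    """Generate one single-region inventory with oracle truth.

    ``industry_mix`` weights the random industry assignment of each
    cohort (default: beef-heavy with the other industries present).
    Deterministic for a fixed seed.
    """
    if n_cohorts < 1:
        raise ValueError("need at least one cohort")
    rng = np.random.default_rng(seed)
    mix = dict(industry_mix) if industry_mix else {
        Industry.BEEF: 0.4, Industry.DAIRY: 0.2,
        Industry.PORK: 0.25, Industry.POULTRY: 0.15,
    }
    industries = list(mix)
    weights = np.array([mix[i] for i in industries], dtype=float)
    weights /= weights.sum()
    crops = _make_crops(rng)
    energy = _make_energy(rng)
    cohorts = []
    for i in range(n_cohorts):
        industry = industries[int(rng.choice(len(industries), p=weights))]
        cohorts.append(_make_cohort(
            rng, industry, region, f"{industry.value}_cohort_{i}", crops,
        ))
    case = SyntheticCase(
        seed=seed, region=region, cohorts=tuple(cohorts), crops=crops,
        energy=energy, gwp=GwpSet(),
        ef_organic=float(rng.uniform(0.005, 0.02)),
        ef_synthetic=float(rng.uniform(0.005, 0.02)),
        sales_adjustment=float(rng.uniform(0.7, 1.2)),
    )
    return _with_truth(case)


def _with_truth(case: SyntheticCase) -> SyntheticCase:
    registry = {c.name: c for c in case.crops}
    complexes: Dict[Industry, CropComplex] = {}
    budgets: Dict[Industry, EmissionBudget] = {}
    for industry in Industry:
        members = case.cohorts_of(industry)
        if not members:
            continue
        areas, pasture = _naive_complex(members, registry)
        complexes[industry] = CropComplex(
            industry=industry, region=case.region,
            areas=areas, pasture_kha=pasture,
        )
        budgets[industry] = _naive_budget(
            members, areas, pasture, registry, case.energy, case.gwp,
            case.ef_organic, case.ef_synthetic, case.sales_adjustment,
            case.region, industry,
        )
    return SyntheticCase(
        **{**case.__dict__,
           "truth_complexes": complexes, "truth_budgets": budgets},
    )


def generate_redistribution_case(
    seed: int,
    fraction: float = 0.10,
    n_cohorts_per_industry: int = 3,
    region: Region = Region.WEST,
) -> RedistributionCase:
    """Paired before/after beef+pork inventories under a
    protein-conserving reallocation.

    The beef diet is forage-heavy enough that the freed perennial area
    always covers the annual-area conversion (ΔrA ≥ 0 by construction);
    the generator enlarges the beef forage ration deterministically if
    a draw would violate that.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    crops = _make_crops(rng)
    registry = {c.name: c for c in crops}
    energy = _make_energy(rng)

    for forage_boost in (1.0, 3.0, 10.0, 40.0):
        draw = np.random.default_rng(rng.integers(0, 2**31))
        beef = [
            _make_cohort(draw, Industry.BEEF, region, f"beef_{i}", crops,
                         forage_boost=forage_boost)
            for i in range(n_cohorts_per_industry)
        ]
        pork = [
            _make_cohort(draw, Industry.PORK, region, f"pork_{i}", crops)
            for i in range(n_cohorts_per_industry)
        ]
        beef_areas, _ = _naive_complex(beef, registry)
        pork_areas, _ = _naive_complex(pork, registry)

        def class_sum(areas: Dict[str, float], cls: LandClass,
                      include_silage_with: Optional[LandClass] = None) -> float:
            total = 0.0
            for crop, area in areas.items():
                c = registry[crop]
                effective = c.land_class
                if crop == "silage_corn" and include_silage_with is not None:
                    effective = include_silage_with
                if effective is cls:
                    total += area
            return total

        # annual-convertible beef area (grain + silage) and perennial area
        beef_annual = class_sum(beef_areas, LandClass.GRAIN,
                                include_silage_with=LandClass.GRAIN)
        beef_perennial = class_sum(beef_areas, LandClass.FORAGE,
                                   include_silage_with=LandClass.GRAIN)
        pork_annual = class_sum(pork_areas, LandClass.GRAIN)

        beef_protein = sum(
            c.population * c.live_weight * _PROTEIN_FACTORS[Industry.BEEF]
            for c in beef) / 1e6
        pork_protein = sum(
            c.population * c.live_weight * _PROTEIN_FACTORS[Industry.PORK]
            for c in pork) / 1e6
        inflation_excess = fraction * beef_protein / pork_protein

        a_p = inflation_excess * pork_annual
        a_g = fraction * beef_annual
        a_f = fraction * beef_perennial
        if a_p - a_g <= a_f:
            break
    else:  # pragma: no cover - boost schedule always suffices
        raise RuntimeError("could not satisfy residual-area invariant")

    def scaled(cohorts: Sequence[CohortSpec], factor: float) -> List[CohortSpec]:
        return [
            CohortSpec(
                industry=c.industry, region=c.region, label=c.label,
                population=c.population * factor, live_weight=c.live_weight,
                diet=dict(c.diet), enteric_ef=c.enteric_ef,
                manure_ch4_ef=c.manure_ch4_ef, manure_n=c.manure_n,
                pasture_kha=c.pasture_kha * factor,
            )
            for c in cohorts
        ]

    common = dict(
        region=region, crops=crops, energy=energy, gwp=GwpSet(),
        ef_organic=float(rng.uniform(0.005, 0.02)),
        ef_synthetic=float(rng.uniform(0.005, 0.02)),
        sales_adjustment=float(rng.uniform(0.7, 1.2)),
    )
    before = _with_truth(SyntheticCase(
        seed=seed, cohorts=tuple(beef + pork), **common))
    after = _with_truth(SyntheticCase(
        seed=seed,
        cohorts=tuple(scaled(beef, 1.0 - fraction)
                      + scaled(pork, 1.0 + inflation_excess)),
        **common))
    return RedistributionCase(
        fraction=fraction, before=before, after=after,
        truth_a_p=a_p, truth_a_g=a_g, truth_a_f=a_f,
    )
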