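"""Protein-equivalent reallocation from beef to pork.

The reallocation is protein-neutral: the pork industry must supply
exactly the protein removed from beef.  With a fraction f of beef
protein P_b displaced onto a pork supply P_p, beef scales by the
deflation factor (1 − f) and pork by the inflation factor
1 + f·P_b/P_p.  Because every emission pathway is linear in herd size,
the same factors scale the industries' GHG budgets.

Land algebra.  The reallocation changes three areas: A_p, new feed
grain for pork; A_g, feed grain (incl. silage) freed by displaced
beef; and A_f, harvested perennial forage freed by displaced beef.
The forage converted to annuals is

    ΔcA = A_p − A_g                                          (1)

and the residual freed forage is

    ΔrA = A_f − ΔcA.                                         (2)

By construction ΔcA + ΔrA = A_f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .lcc import CropComplex
from .types import CropSpec, EmissionBudget, LandClass, Region

__all__ = [
    "ProteinLedger",
    "AreaChange",
    "protein_ledger",
    "scale_budget",
    "net_annual_reduction",
    "area_changes",
    "redistribute_budgets",
]


@dataclass(frozen=True)
class ProteinLedger:
    """Protein bookkeeping for one region's beef→pork reallocation.

    Masses in kt protein.  Factors are carried unrounded; the percent
    properties round to integers only for display, matching inventory
    reporting practice.
    """

    region: Region
    beef_initial: float
    pork_initial: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        if self.pork_initial <= 0:
            raise ZeroDivisionError("pork protein supply must be > 0")
        if self.beef_initial < 0:
            raise ValueError("beef protein must be >= 0")

    @property
    def reallocated(self) -> float:
        """Protein moved from beef to pork, kt."""
        return self.fraction * self.beef_initial

    @property
    def beef_remaining(self) -> float:
        return self.beef_initial - self.reallocated

    @property
    def pork_after(self) -> float:
        return self.pork_initial + self.reallocated

    @property
    def deflation(self) -> float:
        """Beef scale factor, unrounded (e.g. 0.90)."""
        return 1.0 - self.fraction

    @property
    def inflation(self) -> float:
        """Pork scale factor, unrounded (e.g. 1.1774 for the west)."""
        return self.pork_after / self.pork_initial

    @property
    def deflation_pct(self) -> int:
        return round(100 * self.deflation)

    @property
    def inflation_pct(self) -> int:
        return round(100 * self.inflation)


@dataclass(frozen=True)
class AreaChange:
    """Area terms of the reallocation for one region, kha."""

    region: Region
    a_p: float
    a_g: float
    a_f: float

    def __post_init__(self) -> None:
        if self.a_p < 0 or self.a_f < 0:
            raise ValueError(
                "negative A_p or A_f: redistribution direction reversed"
            )

    @property
    def delta_c(self) -> float:
        """Forage converted to annuals (Eq. 1)."""
        return self.a_p - self.a_g

    @property
    def delta_r(self) -> float:
        """Residual freed forage (Eq. 2), floored at zero."""
        raw = self.a_f - self.delta_c
        if raw < 0:
            warnings.warn(
                f"{self.region.value}: residual area negative "
                f"({raw:.3g} kha); clipping to 0", stacklevel=2,
            )
            return 0.0
        return raw


def protein_ledger(
    beef_protein: float, pork_protein: float, fraction: float,
    region: Region = Region.CANADA,
) -> ProteinLedger:
    """Build the reallocation ledger for one region.

    ``fraction`` is the share of beef protein displaced (the study
    default is 0.10, chosen so only the best portion of the beef land
    base is involved).
    """
    return ProteinLedger(
        region=region, beef_initial=beef_protein,
        pork_initial=pork_protein, fraction=fraction,
    )


def scale_budget(budget: EmissionBudget, factor: float) -> EmissionBudget:
    """Componentwise budget scaling — valid because every emission
    pathway is linear in herd size and land area."""
    return budget.scaled(factor)


def net_annual_reduction(
    deducted: EmissionBudget, additional: EmissionBudget
) -> EmissionBudget:
    """Net annual emissions removed by the reallocation: beef deduction
    minus pork addition, componentwise.  Regions must match."""
    if deducted.region != additional.region:
        raise ValueError(
            f"region mismatch: {deducted.region.value} vs "
            f"{additional.region.value}"
        )
    return EmissionBudget(
        ch4=deducted.ch4 - additional.ch4,
        n2o=deducted.n2o - additional.n2o,
        fossil_co2=deducted.fossil_co2 - additional.fossil_co2,
        enteric_ch4=deducted.enteric_ch4 - additional.enteric_ch4,
        region=deducted.region,
        signed=True,
    )


def _grain_and_silage_kha(
    lcc: CropComplex, crops: Iterable[CropSpec]
) -> tuple[float, float]:
    """(grain kha, forage-class-annuals — i.e. silage — plus harvested
    forage kha) split of a complex."""
    registry = {c.name: c for c in crops}
    grain = forage = 0.0
    for crop, area in lcc.areas.items():
        cls = registry[crop].land_class
        if cls is LandClass.GRAIN:
            grain += area
        elif cls is LandClass.FORAGE:
            forage += area
    return grain, forage


def area_changes(
    bcc_before: CropComplex,
    bcc_after: CropComplex,
    pcc_before: CropComplex,
    pcc_after: CropComplex,
    crops: Iterable[CropSpec],
    silage_crops: Iterable[str] = ("silage_corn",),
) -> AreaChange:
    """Area terms from before/after beef (BCC) and pork (PCC) complexes.

    A_p counts the growth of the pork grain area; A_g the shrinkage of
    the beef grain + silage area (silage, an annual, is convertible
    between annual crops and therefore belongs with the grains here);
    A_f the shrinkage of the beef harvested-perennial area, silage
    excluded.
    """
    crops = list(crops)
    silage = set(silage_crops)
    if not (bcc_before.region == bcc_after.region
            == pcc_before.region == pcc_after.region):
        raise ValueError("complexes must share one region")

    registry = {c.name: c for c in crops}

    def split(lcc: CropComplex) -> tuple[float, float]:
        """(annual-convertible kha, harvested perennial kha)."""
        annual = perennial = 0.0
        for crop, area in lcc.areas.items():
            cls = registry[crop].land_class
            if cls is LandClass.GRAIN or crop in silage:
                annual += area
            elif cls is LandClass.FORAGE:
                perennial += area
        return annual, perennial

    beef_annual_before, beef_per_before = split(bcc_before)
    beef_annual_after, beef_per_after = split(bcc_after)
    pork_annual_before, _ = split(pcc_before)
    pork_annual_after, _ = split(pcc_after)

    return AreaChange(
        region=bcc_before.region,
        a_p=pork_annual_after - pork_annual_before,
        a_g=beef_annual_before - beef_annual_after,
        a_f=beef_per_before - beef_per_after,
    )


@dataclass(frozen=True)
class RedistributionResult:
    """Scaled budgets for one region's reallocation."""

    ledger: ProteinLedger
    deducted: EmissionBudget
    additional: EmissionBudget
    net: EmissionBudget


def redistribute_budgets(
    beef_budget: EmissionBudget,
    pork_budget: EmissionBudget,
    ledger: ProteinLedger,
) -> RedistributionResult:
    """Scale baseline budgets by the ledger factors.

    Deducted = fraction × beef baseline; additional = (inflation − 1) ×
    pork baseline, using the unrounded inflation factor.
    """
    deducted = scale_budget(beef_budget, ledger.fraction)
    additional = scale_budget(pork_budget, ledger.inflation - 1.0)
    return RedistributionResult(
        ledger=ledger,
        deducted=deducted,
        additional=additional,
        net=net_annual_reduction(deducted, additional),
    )
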