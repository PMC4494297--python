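"""Livestock crop complex: the feed-supporting land base.

The crop complex of an industry-region is obtained by integrating the
rations of every age-gender cohort over its population (kt feed/y per
crop) and dividing each crop requirement by that crop's average yield
(t/ha) to get the area (kha) needed to grow it.  Grazed pasture has no
meaningful harvest yield and therefore enters as a directly specified
area per cohort, passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

from .types import CohortSpec, CropSpec, Industry, LandClass, Region

__all__ = [
    "CropComplex",
    "feed_requirement",
    "lcc_from_requirements",
    "build_lcc",
    "land_class_summary",
]


@dataclass(frozen=True)
class CropComplex:
    """Per-crop land areas (kha) supporting one industry-region.

    ``pasture_kha`` is grazed area held separately from the harvested
    crops in ``areas``; it contributes to the PASTURE land class.
    """

    industry: Industry
    region: Region
    areas: Mapping[str, float] = field(default_factory=dict)
    pasture_kha: float = 0.0

    def __post_init__(self) -> None:
        for crop, area in self.areas.items():
            if area < 0:
                raise ValueError(f"negative area for crop {crop!r}")
        if self.pasture_kha < 0:
            raise ValueError("negative pasture area")

    def total_kha(self) -> float:
        return sum(self.areas.values()) + self.pasture_kha


def feed_requirement(cohorts: Sequence[CohortSpec]) -> Dict[str, float]:
    """Total annual feed requirement by crop, kt/y.

    Sums population × ration over cohorts, which must all belong to one
    industry-region.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    key = (cohorts[0].industry, cohorts[0].region)
    req: Dict[str, float] = {}
    for c in cohorts:
        if (c.industry, c.region) != key:
            raise ValueError(
                f"cohort {c.label!r} is {c.industry.value}/{c.region.value}, "
                f"expected {key[0].value}/{key[1].value}"
            )
        for crop, kg_per_head in c.diet.items():
            # head × kg/head/y = kg/y; 1 kt = 1e6 kg
            req[crop] = req.get(crop, 0.0) + c.population * kg_per_head / 1e6
    return req


def lcc_from_requirements(
    req: Mapping[str, float],
    crops: Iterable[CropSpec],
    industry: Industry,
    region: Region,
    pasture_kha: float = 0.0,
) -> CropComplex:
    """Convert feed requirements (kt/y) into a crop complex (kha).

    area[crop] = requirement / yield; kt / (t/ha) = kha exactly.
    ``pasture_kha`` is passed through unchanged.
    """
    registry = {c.name: c for c in crops}
    areas: Dict[str, float] = {}
    for crop, kt in req.items():
        if crop not in registry:
            raise KeyError(f"no crop registry entry for {crop!r}")
        spec = registry[crop]
        if spec.yield_t_ha <= 0:
            raise ZeroDivisionError(
                f"crop {crop!r} has non-positive yield; cannot derive area"
            )
        areas[crop] = kt / spec.yield_t_ha
    return CropComplex(industry=industry, region=region, areas=areas,
                       pasture_kha=pasture_kha)


def build_lcc(
    cohorts: Sequence[CohortSpec], crops: Iterable[CropSpec]
) -> CropComplex:
    """Feed requirement + yield division in one step, with per-cohort
    pasture areas accumulated into the complex."""
    req = feed_requirement(cohorts)
    pasture = sum(c.pasture_kha for c in cohorts)
    return lcc_from_requirements(
        req, crops, industry=cohorts[0].industry,
        region=cohorts[0].region, pasture_kha=pasture,
    )


def land_class_summary(
    lcc: CropComplex, crops: Iterable[CropSpec]
) -> Dict[LandClass, float]:
    """Sum complex areas by land class (kha).

    Silage corn is registered as FORAGE and therefore lands there; the
    pork and poultry complexes, being grain-only, summarize to zero
    FORAGE and PASTURE.
    """
    registry = {c.name: c for c in crops}
    out = {cls: 0.0 for cls in LandClass}
    for crop, area in lcc.areas.items():
        if crop not in registry:
            raise KeyError(f"no crop registry entry for {crop!r}")
        out[registry[crop].land_class] += area
    out[LandClass.PASTURE] += lcc.pasture_kha
    return out
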