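"""CSV readers and writers for cohort, diet and crop tables.

Dialect (RFC-4180, header rows):

* ``crops.csv`` — name, land_class (grain/forage/pasture), yield_t_ha,
  n_recommendation (kg N/ha/y)
* ``cohorts.csv`` — industry, region, label, population, live_weight,
  enteric_ef, manure_ch4_ef, manure_n, pasture_kha
* ``diets.csv`` — label, crop, kg_per_head_y (one row per cohort-crop)
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd

from .types import CohortSpec, CropSpec, Industry, LandClass, Region

COHORT_COLUMNS = ["industry", "region", "label", "population",
                  "live_weight", "enteric_ef", "manure_ch4_ef",
                  "manure_n", "pasture_kha"]
DIET_COLUMNS = ["label", "crop", "kg_per_head_y"]
CROP_COLUMNS = ["name", "land_class", "yield_t_ha", "n_recommendation"]


def read_crops(path: str | Path) -> List[CropSpec]:
    frame = pd.read_csv(path, float_precision="round_trip")
    _require(frame, CROP_COLUMNS, path)
    return [
        CropSpec(
            name=row["name"],
            land_class=LandClass(row["land_class"]),
            yield_t_ha=float(row["yield_t_ha"]),
            n_recommendation=float(row["n_recommendation"]),
        )
        for _, row in frame.iterrows()
    ]


def read_cohorts(
    cohorts_path: str | Path, diets_path: str | Path
) -> List[CohortSpec]:
    cohorts = pd.read_csv(cohorts_path, float_precision="round_trip")
    diets = pd.read_csv(diets_path, float_precision="round_trip")
    _require(cohorts, COHORT_COLUMNS, cohorts_path)
    _require(diets, DIET_COLUMNS, diets_path)
    if cohorts.empty:
        raise ValueError(f"no cohorts in {cohorts_path}")
    rations: Dict[str, Dict[str, float]] = {}
    for _, row in diets.iterrows():
        rations.setdefault(row["label"], {})[row["crop"]] = \
            float(row["kg_per_head_y"])
    return [
        CohortSpec(
            industry=Industry(row["industry"]),
            region=Region(row["region"]),
            label=row["label"],
            population=float(row["population"]),
            live_weight=float(row["live_weight"]),
            diet=rations.get(row["label"], {}),
            enteric_ef=float(row["enteric_ef"]),
            manure_ch4_ef=float(row["manure_ch4_ef"]),
            manure_n=float(row["manure_n"]),
            pasture_kha=float(row["pasture_kha"]),
        )
        for _, row in cohorts.iterrows()
    ]


def write_crops(crops: Sequence[CropSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": c.name, "land_class": c.land_class.value,
             "yield_t_ha": c.yield_t_ha,
             "n_recommendation": c.n_recommendation}
            for c in crops
        ],
        columns=CROP_COLUMNS,
    ).to_csv(path, index=False)


def write_cohorts(
    cohorts: Sequence[CohortSpec],
    cohorts_path: str | Path,
    diets_path: str | Path,
) -> None:
    pd.DataFrame(
        [
            {"industry": c.industry.value, "region": c.region.value,
             "label": c.label, "population": c.population,
             "live_weight": c.live_weight, "enteric_ef": c.enteric_ef,
             "manure_ch4_ef": c.manure_ch4_ef, "manure_n": c.manure_n,
             "pasture_kha": c.pasture_kha}
            for c in cohorts
        ],
        columns=COHORT_COLUMNS,
    ).to_csv(cohorts_path, index=False)
    pd.DataFrame(
        [
            {"label": c.label, "crop": crop, "kg_per_head_y": ration}
            for c in cohorts
            for crop, ration in sorted(c.diet.items())
        ],
        columns=DIET_COLUMNS,
    ).to_csv(diets_path, index=False)


def _require(frame: pd.DataFrame, columns: Sequence[str],
             path: str | Path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
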