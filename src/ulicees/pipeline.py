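"""End-to-end runs: annual inventory and the full reallocation study.

The study chain (fixtures mode) is: protein ledger per region →
budget scaling (deducted / additional / net) → area algebra →
residual-land scenarios → soil-carbon losses and payback periods.
Area terms scale linearly with the reallocated fraction, so fractions
other than the packaged study's 0.10 rescale the packaged areas
proportionally.
"""

from __future__ import annotations

import logging
from importlib.metadata import version
from pathlib import Path
from typing import Dict, Mapping, Tuple

import pandas as pd

from . import reports
from .config import RunConfig
from .emissions import EnergyCoefficients, budget_from_inventory
from .fixtures import FixtureTables, load_fixtures
from .io import read_cohorts, read_crops
from .lcc import build_lcc
from .redistribution import (
    RedistributionResult,
    protein_ledger,
    redistribute_budgets,
)
from .scenarios import (
    PaybackResult,
    Scenario,
    default_calibration,
    evaluate_scenarios,
)
from .types import EmissionBudget, GwpSet, Industry, Region

log = logging.getLogger("ulicees")

#: The packaged area tables correspond to this reallocated fraction.
FIXTURE_FRACTION = 0.10


def _log_run(cfg: RunConfig, kind: str) -> None:
    try:
        pkg_version = version("ulicees")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    log.info("%s run: ulicees %s, config %s", kind, pkg_version,
             cfg.config_hash())


def run_inventory(cfg: RunConfig, out_dir: str | Path | None = None
                  ) -> Dict[str, pd.DataFrame]:
    """Annual GHG inventory: per industry-region budgets plus an
    enteric/non-enteric summary.  Writes CSVs and returns the frames."""
    _log_run(cfg, "inventory")
    out_dir = Path(out_dir if out_dir is not None else cfg.out_dir)
    if cfg.uses_fixtures:
        frames = _fixture_inventory()
    else:
        frames = _bottom_up_inventory(cfg)
    reports.write_tables(frames, out_dir)
    return frames


def _fixture_inventory() -> Dict[str, pd.DataFrame]:
    tables = load_fixtures()
    budget_rows = []
    for region in (Region.EAST, Region.WEST):
        for industry in (Industry.BEEF, Industry.PORK):
            b = tables.budget(region, industry, "baseline")
            budget_rows.append({
                "region": region.value, "industry": industry.value,
                "ch4": b.ch4, "n2o": b.n2o, "co2": b.fossil_co2,
                "total": b.total(),
            })
    summary_rows = [
        {"industry": ind.value,
         "total": tables.inventory_value(Region.CANADA, ind)}
        for ind in (Industry.BEEF, Industry.DAIRY, Industry.PORK,
                    Industry.POULTRY)
    ]
    total = tables.inventory_value(Region.CANADA, Industry.ALL, "total")
    enteric = tables.inventory_value(Region.CANADA, Industry.ALL, "enteric")
    summary_rows.append({"industry": "all", "total": total})
    enteric_rows = [
        {"source": "enteric", "total": enteric},
        {"source": "non_enteric", "total": total - enteric},
    ]
    return {
        "budgets": pd.DataFrame(budget_rows),
        "industry_summary": pd.DataFrame(summary_rows),
        "enteric_split": pd.DataFrame(enteric_rows),
    }


def _bottom_up_inventory(cfg: RunConfig) -> Dict[str, pd.DataFrame]:
    crops = read_crops(cfg.inputs.crops)
    cohorts = read_cohorts(cfg.inputs.cohorts, cfg.inputs.diets)
    gwp = GwpSet(gwp_ch4=cfg.gwp.ch4, gwp_n2o=cfg.gwp.n2o)
    # default flat energy coefficients; bottom-up users supply their own
    # via the library API when they have better ones
    energy = EnergyCoefficients(
        fieldwork={c.land_class: 0.15 for c in crops},
        transport={c.land_class: 0.05 for c in crops},
        heating_electricity={c.land_class: 0.05 for c in crops},
        manufacture={c.land_class: 0.10 for c in crops},
    )
    groups: Dict[Tuple[Industry, Region], list] = {}
    for c in cohorts:
        groups.setdefault((c.industry, c.region), []).append(c)
    budget_rows = []
    enteric_total = 0.0
    grand = EmissionBudget.zero()
    for (industry, region), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        lcc = build_lcc(members, crops)
        b = budget_from_inventory(
            members, lcc, crops, energy, gwp,
            cfg.ef_organic, cfg.ef_synthetic, cfg.sales_adjustment,
        )
        budget_rows.append({
            "region": region.value, "industry": industry.value,
            "ch4": b.ch4, "n2o": b.n2o, "co2": b.fossil_co2,
            "enteric_ch4": b.enteric_ch4, "total": b.total(),
        })
        enteric_total += b.enteric_ch4
        grand = grand + b
    enteric_rows = [
        {"source": "enteric", "total": enteric_total},
        {"source": "non_enteric", "total": grand.total() - enteric_total},
    ]
    return {
        "budgets": pd.DataFrame(budget_rows),
        "enteric_split": pd.DataFrame(enteric_rows),
    }


def run_study(cfg: RunConfig, out_dir: str | Path | None = None
              ) -> Dict[str, pd.DataFrame]:
    """Full reallocation study on the packaged tables: ledger, areas,
    budget sections, scenario emissions, soil losses and paybacks."""
    if not cfg.uses_fixtures:
        raise ValueError(
            "the study pipeline runs on the packaged study tables; "
            "bottom-up reallocations use the library API directly"
        )
    _log_run(cfg, "study")
    out_dir = Path(out_dir if out_dir is not None else cfg.out_dir)
    tables = load_fixtures()

    results: Dict[Region, RedistributionResult] = {}
    baselines: Dict[Tuple[Region, str], EmissionBudget] = {}
    net_by_region: Dict[Region, EmissionBudget] = {}
    areas: Dict[Region, Mapping[str, float]] = {}
    scale = cfg.fraction / FIXTURE_FRACTION
    for region in (Region.EAST, Region.WEST):
        ledger = protein_ledger(
            tables.protein(region, Industry.BEEF, "initial"),
            tables.protein(region, Industry.PORK, "initial"),
            cfg.fraction, region,
        )
        beef = tables.budget(region, Industry.BEEF, "baseline")
        pork = tables.budget(region, Industry.PORK, "baseline")
        baselines[(region, "beef")] = beef
        baselines[(region, "pork")] = pork
        results[region] = redistribute_budgets(beef, pork, ledger)
        net_by_region[region] = results[region].net
        areas[region] = {
            key: scale * tables.area_change(region, key)
            for key in ("delta_c", "delta_r", "annuals_s3", "annuals_s4")
        }

    calibration = default_calibration(tables)
    if scale != 1.0:
        # reseeded-annuals areas also scale with the herd change
        calibration = _rescale_extras(calibration, scale)
    paybacks = evaluate_scenarios(
        net_by_region, areas, calibration, benchmark=cfg.benchmark_years,
    )

    frames = {
        "protein_ledger": reports.protein_table(results),
        "area_changes": reports.area_change_table(areas),
        "budget_sections": reports.budget_table(results, baselines),
        "scenario_emissions": reports.scenario_emission_table(
            paybacks, net_by_region),
        "soil_carbon_payback": reports.payback_table(paybacks),
        "summary": reports.scenario_summary(paybacks),
    }
    reports.write_tables(frames, out_dir)
    reports.plot_decay_curve(
        Path(out_dir) / "decay_curve.png",
        horizon=cfg.benchmark_years,
        fraction_at_horizon=cfg.decay_fraction_at_horizon,
    )
    return frames


def _rescale_extras(calibration, scale: float):
    from dataclasses import replace

    from .scenarios import Calibration
    defs = {
        key: replace(sdef, extra_annuals_kha=sdef.extra_annuals_kha * scale)
        for key, sdef in calibration.scenario_defs.items()
    }
    return Calibration(scenario_defs=defs,
                       soil_coeffs=calibration.soil_coeffs)


def study_paybacks(cfg: RunConfig | None = None
                   ) -> Dict[Tuple[Region, Scenario], PaybackResult]:
    """The study's payback results without report writing (library use)."""
    cfg = cfg or RunConfig()
    tables = load_fixtures()
    net_by_region = {}
    areas = {}
    for region in (Region.EAST, Region.WEST):
        ledger = protein_ledger(
            tables.protein(region, Industry.BEEF, "initial"),
            tables.protein(region, Industry.PORK, "initial"),
            cfg.fraction, region,
        )
        result = redistribute_budgets(
            tables.budget(region, Industry.BEEF, "baseline"),
            tables.budget(region, Industry.PORK, "baseline"),
            ledger,
        )
        net_by_region[region] = result.net
        areas[region] = {
            key: tables.area_change(region, key)
            for key in ("delta_c", "delta_r", "annuals_s3", "annuals_s4")
        }
    return evaluate_scenarios(
        net_by_region, areas, default_calibration(tables),
        benchmark=cfg.benchmark_years,
    )
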