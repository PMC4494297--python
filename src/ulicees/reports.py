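"""Report-table builders and the decay-curve plot.

Builders return tidy DataFrames shaped like the study's published
tables; writers emit RFC-4180 CSV.  Row order and float formatting are
deterministic so reports are byte-stable for a fixed configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .redistribution import AreaChange, RedistributionResult
from .scenarios import PaybackResult, Scenario, calibrate_decay_rate, decay_fraction
from .types import EmissionBudget, Region

REGION_ORDER = [Region.EAST, Region.WEST, Region.CANADA]


def protein_table(
    results: Mapping[Region, RedistributionResult]
) -> pd.DataFrame:
    rows = []
    for region in (Region.EAST, Region.WEST):
        ledger = results[region].ledger
        rows.append({
            "region": region.value, "industry": "beef",
            "initial_kt": ledger.beef_initial,
            "reallocated_kt": round(ledger.reallocated, 1),
            "after_kt": round(ledger.beef_remaining, 1),
            "factor_pct": ledger.deflation_pct,
        })
        rows.append({
            "region": region.value, "industry": "pork",
            "initial_kt": ledger.pork_initial,
            "reallocated_kt": round(ledger.reallocated, 1),
            "after_kt": round(ledger.pork_after, 1),
            "factor_pct": ledger.inflation_pct,
        })
    return pd.DataFrame(rows)


def area_change_table(
    areas_by_region: Mapping[Region, Mapping[str, float]]
) -> pd.DataFrame:
    rows = []
    for region in (Region.EAST, Region.WEST):
        a = areas_by_region[region]
        rows.append({
            "region": region.value,
            "delta_c_kha": round(a["delta_c"], 1),
            "initial_freed_kha": round(a["delta_c"] + a["delta_r"], 1),
            "delta_r_kha": round(a["delta_r"], 1),
            "annuals_s3_kha": round(a.get("annuals_s3", 0.0), 1),
            "annuals_s4_kha": round(a.get("annuals_s4", 0.0), 1),
        })
    frame = pd.DataFrame(rows)
    canada = frame.drop(columns="region").sum()
    canada["region"] = Region.CANADA.value
    return pd.concat([frame, canada.to_frame().T], ignore_index=True)[
        frame.columns
    ]


def budget_table(
    results: Mapping[Region, RedistributionResult],
    baselines: Mapping[Tuple[Region, str], EmissionBudget],
) -> pd.DataFrame:
    """Baseline / deducted / additional / net sections, one row per
    region-section with the three gases and their total."""

    def row(region: Region, industry: str, section: str,
            b: EmissionBudget) -> Dict[str, object]:
        return {
            "region": region.value, "industry": industry,
            "section": section,
            "ch4": round(b.ch4, 2), "n2o": round(b.n2o, 2),
            "co2": round(b.fossil_co2, 2), "total": round(b.total(), 2),
        }

    rows = []
    for region in (Region.EAST, Region.WEST):
        for industry in ("beef", "pork"):
            rows.append(row(region, industry, "baseline",
                            baselines[(region, industry)]))
    for region in (Region.EAST, Region.WEST):
        rows.append(row(region, "beef", "deducted", results[region].deducted))
    for region in (Region.EAST, Region.WEST):
        rows.append(row(region, "pork", "additional",
                        results[region].additional))
    for region in (Region.EAST, Region.WEST):
        rows.append(row(region, "all", "net", results[region].net))
    return pd.DataFrame(rows)


def scenario_emission_table(
    paybacks: Mapping[Tuple[Region, Scenario], PaybackResult],
    net_by_region: Mapping[Region, EmissionBudget],
) -> pd.DataFrame:
    rows = []
    for region in REGION_ORDER:
        entry: Dict[str, object] = {"region": region.value}
        for scenario in Scenario:
            r = paybacks[(region, scenario)]
            if region is Region.CANADA:
                net_total = sum(
                    net_by_region[reg].total()
                    for reg in (Region.EAST, Region.WEST)
                )
            else:
                net_total = net_by_region[region].total()
            entry[scenario.value] = round(net_total - r.annual_decrease, 2)
        rows.append(entry)
    return pd.DataFrame(rows)


def payback_table(
    paybacks: Mapping[Tuple[Region, Scenario], PaybackResult]
) -> pd.DataFrame:
    rows = []
    for variable in ("soil_loss_40y", "decrease", "payback_years"):
        for region in REGION_ORDER:
            entry: Dict[str, object] = {
                "variable": variable, "region": region.value,
            }
            for scenario in Scenario:
                r = paybacks[(region, scenario)]
                if variable == "soil_loss_40y":
                    entry[scenario.value] = round(r.soil_loss_40y, 2)
                elif variable == "decrease":
                    entry[scenario.value] = round(r.annual_decrease, 2)
                else:
                    entry[scenario.value] = r.render_payback()
            rows.append(entry)
    return pd.DataFrame(rows)


def scenario_summary(
    paybacks: Mapping[Tuple[Region, Scenario], PaybackResult]
) -> pd.DataFrame:
    """One line per region-scenario with a defined payback period."""
    rows = []
    for region in REGION_ORDER:
        for scenario in Scenario:
            r = paybacks[(region, scenario)]
            if r.payback_years is None:
                continue
            rows.append({
                "region": region.value, "scenario": scenario.value,
                "payback_years": round(r.payback_years, 1),
                "benchmark_years": r.benchmark_years,
                "ratio_to_benchmark": round(r.ratio_to_benchmark, 2),
            })
    return pd.DataFrame(
        rows, columns=["region", "scenario", "payback_years",
                       "benchmark_years", "ratio_to_benchmark"],
    )


def write_tables(tables: Mapping[str, pd.DataFrame],
                 out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def plot_decay_curve(
    path: str | Path,
    horizon: float = 40.0,
    fraction_at_horizon: float = 0.60,
    t_max: float = 120.0,
) -> Path:
    """Plot the exponential SOC stock-change curve with the accounting
    horizon marked; returns the written path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = calibrate_decay_rate(horizon, fraction_at_horizon)
    t = np.linspace(0.0, t_max, 400)
    frac = [decay_fraction(ti, k) for ti in t]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, frac, lw=2)
    ax.axvline(horizon, ls="--", color="grey")
    ax.axhline(fraction_at_horizon, ls=":", color="grey")
    ax.set_xlabel("years since land-use change")
    ax.set_ylabel("fraction of SOC stock change realized")
    ax.set_ylim(0, 1)
    ax.set_title(f"Soil carbon approach to new equilibrium "
                 f"(k = {k:.4f}/y)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
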