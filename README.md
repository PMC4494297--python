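# ulicees

Unified livestock GHG and soil-carbon accounting: annual
CH4 / N2O / fossil-CO2 budgets of livestock industries built from
cohort-level inventories, protein-equivalent reallocation of
production between industries, and carbon-debt **payback periods**
that weigh annual emission savings against the soil organic carbon
lost when perennial forage is converted to annual cropland.

It is written for agro-environmental modellers and land-use policy
analysts who need to ask questions like: *if a tenth of beef protein
were produced as pork instead, what happens to annual GHG emissions,
what happens to soil carbon on the freed forage land, and how many
years until the one repays the other?*

## The model in brief

For each industry–region, the **livestock crop complex** (LCC) is the
land base feeding the herd: integrate each cohort's ration over its
population and divide by crop yields,

    area_c = (Σ_cohorts N_i · ration_i,c) / Y_c .

Annual emissions are linear in herd and land: enteric and manure CH4
as EF × population, N2O from manure N plus the synthetic-N shortfall
against crop recommendations (× 44/28 × GWP), fossil CO2 from per-ha
energy coefficients over the LCC.

Reallocating a fraction *f* of beef protein P_b onto pork supply P_p
scales beef by (1 − f) and pork by 1 + f·P_b/P_p (protein conserved),
and by linearity scales their budgets the same way. The freed land
splits as

    ΔcA = A_p − A_g          (forage converted to annuals)
    ΔrA = A_f − ΔcA          (residual freed forage)

Four scenarios for ΔrA (perennial cover / reseeded annuals / beef with
mixed diet / grass-fed beef) each emit on ΔrA and lose soil carbon on
the converted area over a 40-year horizon (exponential approach to the
new equilibrium, 60% realized at 40 y). The payback period is

    payback = soil-C loss over 40 y / net annual GHG decrease ,

undefined when annual emissions increase.

The package ships the printed tables of a 2001 Canadian beef→pork
study (10% reallocation, East/West regions) as read-only fixtures and
reproduces them end-to-end; the same machinery runs on user-supplied
cohort/diet/crop CSVs.

## Worked example

```sh
ulicees scenarios --out out/
```

prints one line per region-scenario with a defined payback:

```
east s1: payback 0.2 y (ratio to 40 y benchmark: 0.01)
east s2: payback 40.6 y (ratio to 40 y benchmark: 1.01)
east s3: payback 81.9 y (ratio to 40 y benchmark: 2.05)
west s1: payback 3.8 y (ratio to 40 y benchmark: 0.09)
west s2: payback 31.2 y (ratio to 40 y benchmark: 0.78)
west s3: payback 27.7 y (ratio to 40 y benchmark: 0.69)
west s4: payback 58.2 y (ratio to 40 y benchmark: 1.45)
canada s1: payback 3.2 y (ratio to 40 y benchmark: 0.08)
...
```

Leaving the residual forage untouched (s1) repays the small
soil-carbon debt in under 4 years everywhere; reseeding it to annuals
(s2) pays back within the 40-year window in the west (31.2 y) and is
border-line in the east; repopulating with grass-fed cattle (s4)
exceeds the window in the west and never pays back in the east (its
annual emissions increase, so no eastern s4 line appears). The east s3
payback is long because the eastern net annual saving is only
≈0.03 Tg CO2e/y — the denominator is nearly zero.

`out/` also receives the full CSV tables (protein ledger, area
changes, budget sections, scenario emissions, soil-carbon/payback) and
a decay-curve plot. For instance `out/protein_ledger.csv`:

```
region,industry,initial_kt,reallocated_kt,after_kt,factor_pct
east,beef,36.9,3.7,33.2,90
east,pork,157.7,3.7,161.4,102
west,beef,218.8,21.9,196.9,90
west,pork,123.5,21.9,145.4,118
```

i.e. the west must inflate pork output by 18% to replace 10% of its
beef protein, while the east needs only 2%.

Library use mirrors the CLI:

```python
from ulicees import load_fixtures, protein_ledger, redistribute_budgets
from ulicees.types import Industry, Region

t = load_fixtures()
ledger = protein_ledger(t.protein(Region.WEST, Industry.BEEF),
                        t.protein(Region.WEST, Industry.PORK),
                        fraction=0.10, region=Region.WEST)
result = redistribute_budgets(t.budget(Region.WEST, Industry.BEEF),
                              t.budget(Region.WEST, Industry.PORK), ledger)
print(round(result.net.total(), 2))   # 2.04 Tg CO2e/y net annual saving
```

Synthetic inventories with known ground truth (for testing bottom-up
runs) come from `ulicees synth --seed 1 --out dir/` or
`ulicees.synthetic.generate_case`.

## Layout

| module | contents |
|---|---|
| `ulicees.types` | regions, industries, cohorts, crops, budgets, GWPs |
| `ulicees.fixtures` | packaged study tables + integrity checks |
| `ulicees.lcc` | feed requirements → crop complex → land classes |
| `ulicees.emissions` | CH4 / N2O / fossil-CO2 pathways, budget assembly |
| `ulicees.redistribution` | protein ledger, budget scaling, area algebra |
| `ulicees.scenarios` | residual-land scenarios, SOC decay, payback |
| `ulicees.synthetic` | seeded generators with naive-oracle ground truth |
| `ulicees.config`, `ulicees.io`, `ulicees.reports`, `ulicees.pipeline`, `ulicees.cli` | config, CSV I/O, report tables, orchestration, CLI |

See `docs/methods.md` for assumptions, calibration provenance and
known limitations.
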