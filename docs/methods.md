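# Methods

## Scope and model structure

`ulicees` is an accounting model for the greenhouse-gas (GHG) footprint
of livestock production and for land-reallocation scenarios between
industries. It has four layers:

1. **Livestock crop complex (LCC).** Each industry-region is fed by a
   land base obtained by integrating the rations of every age-gender
   cohort over its population and dividing each crop requirement by
   that crop's average yield. Grazed pasture has no meaningful harvest
   yield, so it enters as a directly specified area per cohort rather
   than through yield division. Silage corn, although botanically an
   annual, is classed with the forages because it fills the forage role
   in cattle diets; in the land-conversion algebra (below) it counts
   with the annuals, because it is agronomically convertible between
   annual crops.
2. **Annual emission budgets.** Three gases are tracked per
   industry-region, all expressed in Tg CO2e/y:
   * CH4 — enteric fermentation as per-cohort emission factors ×
     population (factors are inputs supplied per age-gender cohort;
     the gross-energy machinery that produces such factors is outside
     this package). Swine carry a small default factor scaled by
     `(weight / reference_weight)^exponent` (exponent 1 by default).
     Manure methane is likewise EF × population.
   * N2O — crop-specific fertilizer-N recommendations integrated over
     the LCC give the required nitrogen; manure N (per-head excretion ×
     population) supplies the organic pool; the shortfall, multiplied
     by a regional fertilizer-*sales adjustment* scalar (default 1.0),
     is synthetic N. Each pool has its own emission factor in
     kg N2O-N/kg N; N2O-N converts to N2O by 44/28 before the GWP.
   * fossil CO2 — per-hectare energy coefficients by land class
     (fieldwork, transport, heating/electricity, machinery and
     fertilizer manufacture), applied to the LCC area.
   Every pathway is linear in population and area; a whole inventory
   scales proportionally with herd size. GWPs default to 21 (CH4) and
   310 (N2O), the 100-year values in force for inventories around
   2001; both are configurable, and the packaged fixture tables are
   already in CO2e so they do not depend on this choice.
3. **Protein-equivalent reallocation.** Moving a fraction f of beef
   protein P_b onto a pork supply P_p scales beef by (1 − f) and pork
   by 1 + f·P_b/P_p (protein is conserved exactly). By linearity the
   same factors scale the GHG budgets: deducted = f × beef baseline,
   additional = (inflation − 1) × pork baseline. The inflation factor
   is carried unrounded internally and rounded to integer percent only
   in reports — the printed "additional" emissions are only
   reproducible with the unrounded factor. Three area terms follow:
   A_p (new pork feed grain), A_g (beef feed grain + silage freed),
   A_f (beef harvested perennials freed), with the converted area
   ΔcA = A_p − A_g and residual freed forage ΔrA = A_f − ΔcA, so
   ΔcA + ΔrA = A_f identically. ΔrA is floored at zero with a warning
   if a pathological input drives it negative.
4. **Residual-land scenarios and payback.** Four uses of ΔrA are
   evaluated: left in ungrazed perennial forage (S1, zero emissions),
   reseeded to annual crops (S2), repopulated with a mixed
   forage+grain beef herd (S3), or with a mainly grass-fed herd (S4).
   Each scenario emits at a per-ha rate on ΔrA and converts ΔcA (S1),
   ΔcA + ΔrA (S2), or ΔcA plus a scenario-specific reseeded feed-grain
   area (S3/S4) from perennial to annual cover. Soil organic carbon is
   treated as an exhaustible stock relaxing exponentially to a new
   equilibrium; the accounting horizon is 40 years, calibrated so the
   realized fraction of the stock change at the horizon is exactly
   0.60 (k = −ln 0.4 / 40 ≈ 0.0229/y). The payback period is the
   40-year soil-carbon loss divided by the net annual GHG decrease;
   when the annual change is not a decrease the period is undefined
   and rendered `-` in reports, and the ratio to the 40-year benchmark
   is undefined with it.

## Packaged study tables and calibration

The package ships the printed inputs and outputs of a 2001 Canadian
beef→pork reallocation study (10% of beef protein moved to pork, two
reporting regions, East and West, with Canada as their sum) as
read-only CSV tables: protein weights and factors, crop areas before
and after, area-change terms, annual budgets by gas, residual-land
scenario emissions, soil losses and paybacks, plus the headline
inventory aggregates (53 Tg CO2e total, 22 enteric, beef 31, dairy 10,
pork 7, poultry 5). A load-time integrity check verifies Canada =
East + West to within one unit of the printed precision.

Three printed cells are internally inconsistent in the source tables
(the national beef feed-grain "before" row, and the two
reseeded-annuals columns); they are preserved verbatim and whitelisted
in the check (`fixtures.KNOWN_INCONSISTENT`) rather than repaired,
since any repair would be a guess. A related consequence: the eastern
conversion area ΔcA cannot be recovered from the printed eastern crop
areas (eastern feed grain *rises* after the beef reduction), so the
area-algebra validation uses the western cells and takes the printed
eastern area changes as inputs.

Per-region, per-scenario residual emission rates and 40-year soil-loss
coefficients are *back-derived* from the packaged tables at load time
(`scenarios.default_calibration`): rate = printed scenario emission /
ΔrA; coefficient = printed 40-year loss / converted area. They
reproduce the study's accounting by construction and are defaults, not
independent estimates; users with real coefficients supply their own
`ScenarioDef`/`SoilCarbonCoeff` values. The back-derived western
coefficients agree across S1/S3/S4 (≈73 t CO2e/ha) but S2 implies
≈110 t/ha; the source data do not explain the difference, so the
coefficients are kept scenario-specific and no single-coefficient
reconciliation is attempted.

## Numerical conventions

* Units: areas in kha, masses in kt, emissions in Tg CO2e internally;
  per-head quantities in kg/head/y. Conversions happen once, at I/O
  boundaries, and are exact (kt / (t/ha) = kha, etc.).
* Difference budgets (net changes) may be negative and are flagged
  `signed`; inventory budgets enforce non-negativity and
  enteric ≤ total CH4.
* Report tables round masses to 0.1 kt, emissions to 0.01 Tg, factors
  to integer percent, paybacks to 0.1 y; all internal chaining is
  unrounded. Row order and float formatting are deterministic, so
  reports are byte-stable for a fixed configuration.
* Degenerate inputs: a zero reallocation fraction yields identity
  factors, zero area changes and no defined paybacks; zero pork
  protein is a division error; reversed redistribution direction
  (negative A_p or A_f) is a contract violation.

## Reproduction fidelity

Chaining the printed regional baselines through the unrounded factors
reproduces the printed deducted/additional/net rows within ±0.01 Tg
and the defined payback cells within a few percent. Two cells are
limited by the source's own printed rounding rather than by this
implementation: the eastern S3 payback (printed 92.7 y) divides by a
near-zero decrease (printed 0.02 Tg/y) and cannot be recovered from
printed-precision inputs (the chain gives ≈82 y; its decrease matches
the printed value within half a printed unit), and the national S2
decrease (printed 2.02) differs from the sum of its own printed
regional rows (1.99). The test suite asserts exactly these bounds.

## Synthetic data

The generator (`ulicees.synthetic`) builds single-region inventories
with populations log-uniform on [10², 10⁶] head, 2–6 crops per diet
(ruminants forage+grain, monogastrics grain-only), yields and
emission factors in ordinary agronomic ranges, and computes the
expected complex and budget with a naive head-by-head, hectare-by-
hectare loop in base units that shares no code with the engine. Paired
before/after reallocation cases scale the beef herd by (1 − f) and the
pork herd by the protein-conserving inflation factor, so protein
conservation and the area identities hold by construction; the beef
forage ration is enlarged deterministically if a draw would leave the
freed perennial area smaller than the conversion demand. Distributions
are pragmatic ranges, not fitted to any census: passing tests
demonstrate the accounting algebra and unit discipline, not the
realism of any particular national herd.

## Command-line interface and problem sizes

`ulicees inventory|redistribute|scenarios|synth` are thin wrappers
over the library; `redistribute`/`scenarios` run the packaged study
(the reallocated fraction, benchmark horizon, GWPs and emission
factors are configurable; area terms rescale linearly with the
fraction). Arbitrary bottom-up reallocations between user-supplied
herds are done at the library level with `area_changes` and
`redistribute_budgets`. Everything is desk-scale: the full study chain
and the 100-case oracle comparison each run in seconds on one CPU.

## Known limitations

* Tier-2 gross-energy equations, census/diet-survey ingestion and the
  provincial fertilizer-sales reconciliation are out of scope; they
  enter as per-cohort emission factors, user tables and the scalar
  sales adjustment respectively. Default energy coefficients and N2O
  factors shipped for bottom-up runs are placeholders, flagged
  non-authoritative.
* Soil carbon uses fixed 40-year stock-change quantities, not a
  process model; land quality screening behind the 10% cap is not
  modelled.
* Housing-related energy use is folded into the per-ha energy
  coefficients rather than tracked separately.
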