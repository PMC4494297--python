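"""Gas-pathway arithmetic and budget assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulicees.emissions import (
    EnergyCoefficients,
    NitrogenBalance,
    assemble_budget,
    budget_from_inventory,
    enteric_ch4,
    fossil_co2,
    manure_ch4,
    n2o_emissions,
    nitrogen_balance,
    swine_enteric_ef,
)
from ulicees.lcc import CropComplex, build_lcc
from ulicees.types import CohortSpec, CropSpec, GwpSet, Industry, LandClass, Region

BARLEY = CropSpec("barley", LandClass.GRAIN, 4.0, 80.0)
HAY = CropSpec("hay", LandClass.FORAGE, 5.0, 20.0)
REGISTRY = [BARLEY, HAY,
            CropSpec("pasture", LandClass.PASTURE, 0.0, 0.0)]

FLAT_ENERGY = EnergyCoefficients(
    fieldwork={cls: 0.25 for cls in LandClass},
    transport={cls: 0.25 for cls in LandClass},
    heating_electricity={cls: 0.25 for cls in LandClass},
    manufacture={cls: 0.25 for cls in LandClass},
)


def cohort(population, enteric=0.0, manure=0.0, manure_n=0.0, diet=None,
           industry=Industry.BEEF, label="c"):
    return CohortSpec(industry=industry, region=Region.WEST, label=label,
                      population=population, live_weight=500.0,
                      diet=diet or {}, enteric_ef=enteric,
                      manure_ch4_ef=manure, manure_n=manure_n)


def test_enteric_ch4_unit_arithmetic(gwp):
    # 1,000 head × 100 kg CH4/head/y × GWP 21 = 0.0021 Tg CO2e
    assert enteric_ch4([cohort(1000, enteric=100.0)], gwp) \
        == pytest.approx(0.0021)
    assert enteric_ch4([cohort(0, enteric=100.0)], gwp) == 0.0


def test_enteric_ch4_multi_cohort_matches_head_by_head_sum(gwp):
    cohorts = [cohort(n, enteric=ef, label=f"c{n}")
               for n, ef in [(123, 55.0), (4567, 71.5), (89, 2.0)]]
    expected = sum(c.population * c.enteric_ef for c in cohorts) \
        * gwp.gwp_ch4 / 1e9
    assert enteric_ch4(cohorts, gwp) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "base, weight, reference, expected",
    [(1.5, 100.0, 100.0, 1.5), (1.5, 50.0, 100.0, 0.75),
     (1.5, 0.0, 100.0, 0.0)],
)
def test_swine_ef_scales_linearly_with_weight(base, weight, reference,
                                              expected):
    assert swine_enteric_ef(base, weight, reference) \
        == pytest.approx(expected)


def test_swine_ef_rejects_bad_weights_and_supports_exponent():
    with pytest.raises(ValueError):
        swine_enteric_ef(1.5, 50.0, 0.0)
    assert swine_enteric_ef(1.5, 50.0, 100.0, exponent=0.75) \
        == pytest.approx(1.5 * 0.5 ** 0.75)


def test_manure_ch4_unit_arithmetic(gwp):
    # 10,000 head × 4 kg/head/y × 21 = 0.00084 Tg CO2e
    assert manure_ch4([cohort(10000, manure=4.0)], gwp) \
        == pytest.approx(0.00084)
    assert manure_ch4([cohort(10000, manure=0.0)], gwp) == 0.0


def test_hogs_emit_small_but_nonzero_enteric_methane(gwp):
    """Swine are non-ruminant but still carry a weight-corrected
    enteric factor."""
    ef = swine_enteric_ef(1.5, 90.0, 60.0)
    hogs = cohort(1_000_000, enteric=ef, industry=Industry.PORK)
    assert 0 < enteric_ch4([hogs], gwp) < 1.0


@pytest.mark.parametrize(
    "organic, recommended, adjustment, expected_synthetic",
    [(10.0, 25.0, 1.0, 15.0), (30.0, 25.0, 1.0, 0.0),
     (10.0, 25.0, 0.8, 12.0)],
)
def test_nitrogen_balance_invariant(organic, recommended, adjustment,
                                    expected_synthetic):
    nb = NitrogenBalance(organic_n=organic, recommended_n=recommended,
                         sales_adjustment=adjustment)
    assert nb.synthetic_n == pytest.approx(expected_synthetic)


def test_nitrogen_balance_integrates_manure_and_recommendations():
    cohorts = [cohort(100_000, manure_n=50.0, diet={"barley": 1000.0})]
    lcc = build_lcc(cohorts, REGISTRY)
    nb = nitrogen_balance(cohorts, lcc, REGISTRY, sales_adjustment=1.0)
    assert nb.organic_n == pytest.approx(5.0)          # 1e5 × 50 kg = 5 kt
    # 100 kt barley / 4 t/ha = 25 kha × 80 kg/ha = 2 kt N
    assert nb.recommended_n == pytest.approx(2.0)
    assert nb.synthetic_n == 0.0


def test_nitrogen_balance_names_missing_recommendation():
    lcc = CropComplex(Industry.BEEF, Region.WEST, areas={"ghost": 1.0})
    with pytest.raises(KeyError, match="ghost"):
        nitrogen_balance([cohort(1)], lcc, REGISTRY)


def test_n2o_hand_oracle(gwp):
    # 100 kt synthetic N × EF 0.01 × 44/28 × 310 / 1e3 = 0.487 Tg
    nb = NitrogenBalance(organic_n=0.0, recommended_n=100.0)
    value = n2o_emissions(nb, ef_organic=0.5e-3, ef_synthetic=0.01, gwp=gwp)
    assert value == pytest.approx(100 * 0.01 * (44 / 28) * 310 / 1e3,
                                  rel=1e-12)
    assert value == pytest.approx(0.487, abs=5e-4)


def test_n2o_zero_and_linearity(gwp):
    zero = NitrogenBalance(0.0, 0.0)
    assert n2o_emissions(zero, 0.01, 0.01, gwp) == 0.0
    nb1 = NitrogenBalance(10.0, 40.0)
    nb2 = NitrogenBalance(20.0, 80.0)
    assert n2o_emissions(nb2, 0.01, 0.012, gwp) == pytest.approx(
        2 * n2o_emissions(nb1, 0.01, 0.012, gwp))
    with pytest.raises(ValueError):
        n2o_emissions(nb1, ef_organic=1.5, ef_synthetic=0.01, gwp=gwp)


def test_fossil_co2_per_class_rates():
    lcc = CropComplex(Industry.PORK, Region.EAST, areas={"barley": 100.0})
    # 100 kha × 1.0 t/ha total = 0.1 Tg
    assert fossil_co2(lcc, FLAT_ENERGY, REGISTRY) == pytest.approx(0.1)
    empty = CropComplex(Industry.PORK, Region.EAST, areas={})
    assert fossil_co2(empty, FLAT_ENERGY, REGISTRY) == 0.0


def test_fossil_co2_mixed_classes_equal_elementwise_sum():
    lcc = CropComplex(Industry.BEEF, Region.WEST,
                      areas={"barley": 40.0, "hay": 60.0},
                      pasture_kha=10.0)
    expected = (40.0 + 60.0 + 10.0) * 1.0 / 1e3
    assert fossil_co2(lcc, FLAT_ENERGY, REGISTRY) \
        == pytest.approx(expected)


def test_fossil_co2_missing_class_coefficient_is_named():
    grain_only = EnergyCoefficients(fieldwork={LandClass.GRAIN: 0.2})
    lcc = CropComplex(Industry.BEEF, Region.WEST, areas={"hay": 1.0})
    with pytest.raises(KeyError, match="forage"):
        fossil_co2(lcc, grain_only, REGISTRY)


def test_assemble_budget_keeps_enteric_split():
    b = assemble_budget(enteric=14.0, manure=3.0, n2o=6.0, fossil=3.0,
                        region=Region.WEST, industry=Industry.BEEF)
    assert b.total() == pytest.approx(26.0)
    assert b.enteric_ch4 == 14.0
    assert b.non_enteric == pytest.approx(12.0)
    zero = assemble_budget(0, 0, 0, 0, Region.EAST, Industry.PORK)
    assert zero.total() == 0.0
    with pytest.raises(ValueError):
        assemble_budget(-1, 0, 0, 0, Region.EAST, Industry.PORK)


@given(f=st.floats(0.1, 4.0))
@settings(max_examples=30, deadline=None)
def test_whole_inventory_budget_is_linear_in_herd_size(f, gwp):
    cohorts = [cohort(50_000, enteric=60.0, manure=8.0, manure_n=40.0,
                      diet={"barley": 900.0, "hay": 2500.0})]
    scaled = [
        CohortSpec(industry=c.industry, region=c.region, label=c.label,
                   population=c.population * f, live_weight=c.live_weight,
                   diet=dict(c.diet), enteric_ef=c.enteric_ef,
                   manure_ch4_ef=c.manure_ch4_ef, manure_n=c.manure_n)
        for c in cohorts
    ]
    base = budget_from_inventory(cohorts, build_lcc(cohorts, REGISTRY),
                                 REGISTRY, FLAT_ENERGY, gwp)
    bigger = budget_from_inventory(scaled, build_lcc(scaled, REGISTRY),
                                   REGISTRY, FLAT_ENERGY, gwp)
    assert bigger.total() == pytest.approx(base.total() * f, rel=1e-9)
    assert bigger.n2o == pytest.approx(base.n2o * f, rel=1e-9)
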