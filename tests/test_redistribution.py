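"""Protein ledger, budget scaling, and the area algebra."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulicees.lcc import CropComplex
from ulicees.redistribution import (
    area_changes,
    net_annual_reduction,
    protein_ledger,
    redistribute_budgets,
    scale_budget,
)
from ulicees.types import (
    CropSpec,
    EmissionBudget,
    Industry,
    LandClass,
    Region,
)

REGISTRY = [
    CropSpec("feed_grain", LandClass.GRAIN, 3.0, 70.0),
    CropSpec("silage_corn", LandClass.FORAGE, 9.0, 60.0),
    CropSpec("hay", LandClass.FORAGE, 4.0, 15.0),
]


def test_western_ledger_matches_printed_factors():
    ledger = protein_ledger(218.8, 123.5, 0.10, Region.WEST)
    assert ledger.reallocated == pytest.approx(21.9, abs=0.1)
    assert ledger.beef_remaining == pytest.approx(197.0, abs=0.1)
    assert ledger.deflation_pct == 90
    assert ledger.inflation_pct == 118
    # unrounded inflation carries the extra decimals used downstream
    assert ledger.inflation == pytest.approx(1 + 21.88 / 123.5, rel=1e-9)


def test_eastern_ledger_matches_printed_factors():
    ledger = protein_ledger(36.9, 157.7, 0.10, Region.EAST)
    assert ledger.reallocated == pytest.approx(3.7, abs=0.05)
    assert ledger.inflation_pct == 102
    assert ledger.deflation_pct == 90


def test_zero_fraction_is_identity():
    ledger = protein_ledger(100.0, 50.0, 0.0)
    assert ledger.inflation_pct == 100
    assert ledger.deflation_pct == 100
    assert ledger.reallocated == 0.0


def test_zero_pork_supply_is_a_division_error():
    with pytest.raises(ZeroDivisionError):
        protein_ledger(100.0, 0.0, 0.10)


@given(beef=st.floats(0.1, 1000), pork=st.floats(0.1, 1000),
       fraction=st.floats(0.001, 0.999))
@settings(max_examples=80, deadline=None)
def test_protein_is_conserved_exactly(beef, pork, fraction):
    ledger = protein_ledger(beef, pork, fraction)
    assert ledger.beef_remaining + ledger.pork_after \
        == pytest.approx(beef + pork, rel=1e-12)
    assert ledger.reallocated == pytest.approx(fraction * beef, rel=1e-12)


def west_beef():
    return EmissionBudget(14.71, 8.32, 2.78, region=Region.WEST,
                          industry=Industry.BEEF)


def west_pork():
    return EmissionBudget(1.46, 0.77, 0.83, region=Region.WEST,
                          industry=Industry.PORK)


def test_scale_budget_reproduces_deducted_and_additional_rows():
    deducted = scale_budget(west_beef(), 0.10)
    assert deducted.total() == pytest.approx(2.58, abs=0.01)
    ledger = protein_ledger(218.8, 123.5, 0.10, Region.WEST)
    additional = scale_budget(west_pork(), ledger.inflation - 1.0)
    assert additional.total() == pytest.approx(0.54, abs=0.01)
    same = scale_budget(west_beef(), 1.0)
    assert same == west_beef()
    with pytest.raises(ValueError):
        scale_budget(west_beef(), -0.1)


def test_net_annual_reduction_matches_printed_rows():
    ledger = protein_ledger(218.8, 123.5, 0.10, Region.WEST)
    result = redistribute_budgets(west_beef(), west_pork(), ledger)
    assert result.net.total() == pytest.approx(2.04, abs=0.01)

    east_ledger = protein_ledger(36.9, 157.7, 0.10, Region.EAST)
    east = redistribute_budgets(
        EmissionBudget(2.64, 2.06, 0.49, region=Region.EAST),
        EmissionBudget(1.62, 1.44, 0.92, region=Region.EAST),
        east_ledger,
    )
    assert east.net.total() == pytest.approx(0.43, abs=0.01)


def test_net_reduction_of_equal_budgets_is_zero_and_regions_must_match():
    b = west_beef()
    net = net_annual_reduction(b, b)
    assert net.total() == 0.0
    east = EmissionBudget(1.0, 1.0, 1.0, region=Region.EAST)
    with pytest.raises(ValueError):
        net_annual_reduction(b, east)


@given(x=st.floats(0, 3), y=st.floats(0, 3))
@settings(max_examples=50, deadline=None)
def test_scaling_is_additive_in_the_factor(x, y):
    b = west_beef()
    combined = scale_budget(b, x + y)
    split = scale_budget(b, x) + scale_budget(b, y)
    assert combined.total() == pytest.approx(split.total(), rel=1e-12,
                                             abs=1e-12)


def bcc(grain, silage, hay):
    return CropComplex(Industry.BEEF, Region.WEST,
                       areas={"feed_grain": grain, "silage_corn": silage,
                              "hay": hay})


def pcc(grain):
    return CropComplex(Industry.PORK, Region.WEST,
                       areas={"feed_grain": grain})


def test_western_area_algebra_from_printed_crop_areas():
    """A_p = 1,932 − 1,641; A_g = (1,818+42) − (1,636+38);
    A_f = 4,944 − 4,449; the converted area lands on the printed
    104.7 kha within integer-rounding slack."""
    change = area_changes(
        bcc_before=bcc(1818, 42, 4944), bcc_after=bcc(1636, 38, 4449),
        pcc_before=pcc(1641), pcc_after=pcc(1932),
        crops=REGISTRY,
    )
    assert change.a_p == pytest.approx(291)
    assert change.a_g == pytest.approx(186)
    assert change.delta_c == pytest.approx(104.7, abs=0.5)
    assert change.a_f == pytest.approx(494.4, abs=0.7)
    assert change.delta_r == pytest.approx(389.7, abs=1.0)


def test_identical_phases_give_zero_change():
    change = area_changes(bcc(100, 10, 400), bcc(100, 10, 400),
                          pcc(50), pcc(50), REGISTRY)
    assert (change.a_p, change.a_g, change.a_f) == (0.0, 0.0, 0.0)
    assert change.delta_c == 0.0 and change.delta_r == 0.0


def test_reversed_direction_is_a_contract_violation():
    with pytest.raises(ValueError):
        area_changes(bcc(100, 10, 400), bcc(100, 10, 450),
                     pcc(50), pcc(50), REGISTRY)


def test_negative_residual_clips_with_warning():
    # pork grain grows far beyond the freed beef area
    with pytest.warns(UserWarning, match="clipping"):
        change = area_changes(bcc(100, 0, 10), bcc(90, 0, 5),
                              pcc(50), pcc(500), REGISTRY)
        assert change.delta_r == 0.0


@given(
    grain=st.floats(10, 2000), silage=st.floats(0, 200),
    hay=st.floats(500, 5000), pork_grain=st.floats(10, 2000),
    f=st.floats(0.01, 0.5), excess=st.floats(0.0, 0.2),
)
@settings(max_examples=60, deadline=None)
def test_area_identity_delta_c_plus_delta_r_is_a_f(
    grain, silage, hay, pork_grain, f, excess
):
    """Eq.-style identity holds whenever the residual is not clipped."""
    change = area_changes(
        bcc(grain, silage, hay),
        bcc(grain * (1 - f), silage * (1 - f), hay * (1 - f)),
        pcc(pork_grain), pcc(pork_grain * (1 + excess)),
        REGISTRY,
    )
    if change.a_f - (change.a_p - change.a_g) >= 0:
        assert change.delta_c + change.delta_r \
            == pytest.approx(change.a_f, rel=1e-9, abs=1e-9)
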