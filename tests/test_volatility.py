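"""Vapor-pressure model, RVI conversion, categories, partitioning."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volindex import (
    CLEAN_ATMOSPHERE,
    POLLUTED_ATMOSPHERE,
    SOIL,
    ContributionTable,
    EnvironmentProfile,
    assign_category,
    calc_vol,
    log10_vapor_pressure,
    parse_smiles,
    partition_fraction,
    rvi_from_log10p,
)
from volindex.group_counting import COUNTED_GROUPS
from volindex.volatility import (
    GAS_CONSTANT_L_ATM,
    STANDARD_TEMPERATURE_K,
    CATEGORIES,
    ContributionError,
)

RT = GAS_CONSTANT_L_ATM * STANDARD_TEMPERATURE_K


class TestLog10VaporPressure:
    def test_zero_counts_gives_constant(self, table):
        assert log10_vapor_pressure({}, table) == pytest.approx(1.79)

    def test_propane(self, table):
        assert log10_vapor_pressure({"carbon": 3}, table) == pytest.approx(0.476)

    def test_methanol(self, table):
        counts = {"carbon": 1, "hydroxyl": 1}
        assert log10_vapor_pressure(counts, table) == pytest.approx(-0.878)

    def test_unknown_group_is_configuration_error(self, table):
        with pytest.raises(ContributionError, match="frobnicate"):
            log10_vapor_pressure({"frobnicate": 1}, table)

    @pytest.mark.parametrize("group", COUNTED_GROUPS)
    def test_linearity_in_every_group(self, table, group):
        """Adding one occurrence of group g shifts log10P by exactly b_g."""
        base = {"carbon": 4, group: 1}
        plus = {"carbon": 4, group: 2}
        assert log10_vapor_pressure(plus, table) - log10_vapor_pressure(
            base, table
        ) == pytest.approx(table[group])

    @pytest.mark.parametrize("group", COUNTED_GROUPS)
    def test_counted_terms_never_increase_volatility(self, table, group):
        assert table[group] < 0

    @given(
        counts=st.dictionaries(
            st.sampled_from(list(COUNTED_GROUPS)), st.integers(0, 10), max_size=6
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_equals_direct_sum(self, counts):
        table = ContributionTable.default()
        expected = table.b0 + sum(v * table[g] for g, v in counts.items())
        assert log10_vapor_pressure(counts, table) == pytest.approx(expected)


class TestRvi:
    def test_propane_reference_value(self):
        assert rvi_from_log10p(0.476, 44.0956) == pytest.approx(9.73, abs=0.005)

    def test_mass_equal_rt_cancels(self):
        for x in (-5.0, 0.0, 3.2):
            assert rvi_from_log10p(x, RT) == pytest.approx(x + 9)

    def test_methylamine(self):
        assert rvi_from_log10p(0.322, 31.0571) == pytest.approx(9.43, abs=0.005)

    @pytest.mark.parametrize("mass", [0.0, -1.0])
    def test_nonpositive_mass_rejected(self, mass):
        with pytest.raises(ValueError):
            rvi_from_log10p(0.0, mass)


class TestAssignCategory:
    @pytest.mark.parametrize(
        "rvi, env, expected",
        [
            (9.73, CLEAN_ATMOSPHERE, "high"),
            (1.0, CLEAN_ATMOSPHERE, "moderate"),
            (-1.0, CLEAN_ATMOSPHERE, "low"),
            (-5.0, CLEAN_ATMOSPHERE, "nonvolatile"),
            (9.73, SOIL, "high"),
            (5.93, SOIL, "moderate"),
            (1.0, POLLUTED_ATMOSPHERE, "low"),
            (3.0, POLLUTED_ATMOSPHERE, "moderate"),
        ],
    )
    def test_examples(self, rvi, env, expected):
        assert assign_category(rvi, env) == expected

    @pytest.mark.parametrize("env", [CLEAN_ATMOSPHERE, POLLUTED_ATMOSPHERE, SOIL])
    def test_boundaries_go_to_upper_bin(self, env):
        assert assign_category(env.low_threshold, env) == "low"
        assert assign_category(env.moderate_threshold, env) == "moderate"
        assert assign_category(env.high_threshold, env) == "high"

    @given(rvi=st.floats(-40, 20, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_total_and_monotone(self, rvi):
        for env in (CLEAN_ATMOSPHERE, POLLUTED_ATMOSPHERE, SOIL):
            cat = assign_category(rvi, env)
            assert cat in CATEGORIES
            higher = assign_category(rvi + 1.0, env)
            assert CATEGORIES.index(higher) >= CATEGORIES.index(cat)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_category(bad)

    def test_custom_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            EnvironmentProfile("bad", 2.0, 0.0, 4.0)


class TestPartitionFraction:
    def test_equal_concentrations_give_half(self):
        assert partition_fraction(1.0, 1.0) == 0.5
        assert partition_fraction(123.4, 123.4) == 0.5

    def test_zero_cstar_gives_one(self):
        assert partition_fraction(0.0, 5.0) == 1.0

    def test_direct_arithmetic(self):
        assert partition_fraction(100.0, 1.0) == pytest.approx(1 / 101)

    @given(
        c_star=st.floats(0, 1e6, allow_nan=False),
        c_total=st.floats(1e-6, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone_decreasing(self, c_star, c_total):
        xi = partition_fraction(c_star, c_total)
        assert 0 < xi <= 1
        assert partition_fraction(c_star + 1.0, c_total) < xi
        assert (xi == 0.5) == (c_star == c_total)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            partition_fraction(1.0, 0.0)


class TestCalcVol:
    def test_propane_end_to_end(self):
        est = calc_vol(parse_smiles("CCC", id="propane"))
        assert est.ok
        assert est.log10_p == pytest.approx(0.476)
        assert est.rvi == pytest.approx(9.73, abs=0.005)
        assert est.category == "high"
        assert est.contributions["carbon"] == pytest.approx(3 * -0.438)

    def test_r_group_record_is_uncalculable_not_error(self):
        est = calc_vol(parse_smiles("CO*", id="stub"))
        assert est.status == "uncalculable"
        assert est.reason == "R group"
        assert est.rvi is None and est.category is None

    def test_phenol_full_pipeline(self):
        est = calc_vol(parse_smiles("Oc1ccccc1", id="phenol"))
        assert est.log10_p == pytest.approx(-3.653)
        assert est.rvi == pytest.approx(5.93, abs=0.005)
        assert est.category == "high"

    def test_rvi_identity_links_log10p_and_mass(self, calculable_cases):
        """rvi == log10_p + log10(M/RT) + 9 for every computed estimate."""
        for case in calculable_cases:
            rec = case.make_record()
            est = calc_vol(rec)
            assert est.rvi == pytest.approx(
                est.log10_p + math.log10(rec.mass / RT) + 9, abs=1e-9
            )

    def test_terms_table_is_overridable(self):
        table = ContributionTable.default().with_terms(thiol=-1.0)
        est = calc_vol(parse_smiles("CS", id="mesh"), table=table)
        assert est.log10_p == pytest.approx(1.79 - 0.438 - 1.0)
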