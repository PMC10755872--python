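"""Functional-group counting: oracle suite, masking, correction rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volindex.chem_io import parse_smiles
from volindex.group_counting import (
    COUNTED_GROUPS,
    NOT_COUNTED_GROUPS,
    FunctionalGroupCounts,
    _match_pattern_groups,
    apply_count_corrections,
    count_groups,
    count_raw_groups,
    default_registry,
    non_aromatic_cc_double_bonds,
)


def _ids(suite):
    return [c.name for c in suite]


def test_registry_covers_every_group_once():
    reg = default_registry()
    ids = [g.group_id for g in reg]
    assert len(ids) == len(set(ids))
    assert len(ids) == 31  # 24 counted + 7 carried but not counted
    assert set(COUNTED_GROUPS) | NOT_COUNTED_GROUPS == set(ids)
    assert len(COUNTED_GROUPS) == 24
    assert NOT_COUNTED_GROUPS == {
        "hydroperoxide",
        "nitrophenol",
        "nitroester",
        "ether_alicyclic",
        "ether_aromatic",
        "amine_aromatic",
        "phosphate",
    }


def test_oracle_suite_counts_match_hand_enumeration(calculable_cases):
    """Every builtin fixture's corrected counts equal the hand enumeration."""
    for case in calculable_cases:
        counts = count_groups(case.make_record())
        assert counts.nonzero() == case.expected_counts, case.name


def test_not_counted_groups_always_zero(calculable_cases):
    for case in calculable_cases:
        counts = count_groups(case.make_record())
        assert all(counts[g] == 0 for g in NOT_COUNTED_GROUPS), case.name


@pytest.mark.parametrize(
    "smiles, expected_raw",
    [
        # Kekulé benzene carries 3 C=C and 1 ring that is also aromatic
        ("c1ccccc1", {"carbon": 6, "ring_raw": 1, "aromatic_ring": 1, "cdb_raw": 3}),
        ("CCC", {"carbon": 3}),
        # ester precedence masks its oxygens from ether/ketone patterns
        ("CCOC(C)=O", {"carbon": 4, "ester": 1}),
    ],
)
def test_count_raw_groups_examples(smiles, expected_raw):
    raw = count_raw_groups(parse_smiles(smiles).mol)
    assert raw.nonzero() == expected_raw


@pytest.mark.parametrize(
    "raw, expected",
    [
        (
            {"aromatic_ring": 1, "ring_raw": 1, "cdb_raw": 3},
            {"aromatic_ring": 1, "non_aromatic_ring": 0, "carbon_double_bond": 0},
        ),
        ({"phenol": 1, "hydroxyl_raw": 1}, {"phenol": 1, "hydroxyl": 0}),
        ({"ring_raw": 1, "aromatic_ring": 0}, {"non_aromatic_ring": 1}),
        (
            {"phosphoric_acid_raw": 1, "phosphoric_ester": 1},
            {"phosphoric_acid": 0, "phosphoric_ester": 1},
        ),
        # flooring: pyridine-like Kekulé count below 3 per aromatic ring
        ({"aromatic_ring": 1, "cdb_raw": 2}, {"carbon_double_bond": 0}),
    ],
)
def test_correction_rules(raw, expected):
    out = apply_count_corrections(FunctionalGroupCounts(raw))
    for key, val in expected.items():
        assert out[key] == val


@given(
    st.fixed_dictionaries(
        {},
        optional={
            "ring_raw": st.integers(0, 6),
            "aromatic_ring": st.integers(0, 4),
            "cdb_raw": st.integers(0, 12),
            "hydroxyl_raw": st.integers(0, 8),
            "phenol": st.integers(0, 4),
            "phosphoric_acid_raw": st.integers(0, 3),
            "phosphoric_ester": st.integers(0, 3),
            "carbon": st.integers(0, 20),
            "ester": st.integers(0, 3),
        },
    )
)
@settings(max_examples=100, deadline=None)
def test_corrections_idempotent_and_nonnegative(raw):
    once = apply_count_corrections(FunctionalGroupCounts(raw))
    twice = apply_count_corrections(once)
    assert dict(once) == dict(twice)
    assert all(v >= 0 for v in once.values())


def test_masking_no_atom_shared_between_groups(calculable_cases):
    """No atom participates in two precedence-ordered pattern groups, apart
    from the two raw/corrected pairs resolved by explicit correction rules."""
    exempt_pairs = {
        frozenset({"phenol", "hydroxyl"}),
        frozenset({"phosphoric_ester", "phosphoric_acid"}),
    }
    for case in calculable_cases:
        rec = case.make_record()
        matches = _match_pattern_groups(rec.mol, default_registry())
        groups = list(matches)
        for i, g1 in enumerate(groups):
            atoms1 = set().union(*matches[g1]) if matches[g1] else set()
            for g2 in groups[i + 1 :]:
                if frozenset({g1, g2}) in exempt_pairs:
                    continue
                atoms2 = set().union(*matches[g2]) if matches[g2] else set()
                assert not (atoms1 & atoms2), (case.name, g1, g2)


def test_kekule_arithmetic_agrees_with_direct_nonaromatic_count(calculable_cases):
    """cdb_raw - 3 x aromatic rings (floored) equals the directly counted
    non-aromatic C=C for all fixtures."""
    for case in calculable_cases:
        rec = case.make_record()
        raw = count_raw_groups(rec.mol)
        corrected = max(raw["cdb_raw"] - 3 * raw["aromatic_ring"], 0)
        direct = non_aromatic_cc_double_bonds(rec.mol)
        # Fused aromatics share Kekulé double bonds across rings, so the
        # subtraction can only undershoot the direct count after flooring.
        if raw["aromatic_ring"] <= 1:
            assert corrected == direct, case.name
        else:
            assert corrected <= direct, case.name


def test_count_groups_requires_structure():
    from volindex.chem_io import MoleculeRecord

    with pytest.raises(ValueError, match="no structure"):
        count_groups(MoleculeRecord(id="x", mol=None))


@pytest.mark.parametrize(
    "smiles, expected",
    [
        ("Oc1ccccc1", {"carbon": 6, "aromatic_ring": 1, "phenol": 1}),
        ("CC(O)=O", {"carbon": 2, "carboxylic_acid": 1}),
        ("OCC(O)CO", {"carbon": 3, "hydroxyl": 3}),
        # sugar-like ring oxygen counts as a generic ether
        ("C1CCOC1", {"carbon": 4, "non_aromatic_ring": 1, "ether": 1}),
        # aromatic amine yields no amine count at all
        ("Nc1ccccc1", {"carbon": 6, "aromatic_ring": 1}),
        # hydroperoxide is carried but never counted (neither peroxide nor hydroxyl)
        ("COO", {"carbon": 1}),
    ],
)
def test_count_groups_spot_checks(smiles, expected):
    assert count_groups(parse_smiles(smiles)).nonzero() == expected
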