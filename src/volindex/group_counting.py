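"""Counting volatility-relevant functional groups.

The counter walks a precedence-ordered registry of SMARTS patterns
(:func:`default_registry`, loaded from ``data/groups.yaml``).  Earlier
patterns mask their matched atoms from later ones, so composite groups
(carboxylic acid, ester, amide, ...) are never additionally counted as the
simpler groups they contain (hydroxyl, ether, ketone, amine).

Four overlaps are deliberately *not* resolved by masking but by explicit
correction rules applied afterwards (:func:`apply_count_corrections`):

* every aromatic ring is also a ring           -> subtract
* every phenol is also a hydroxyl              -> subtract
* a Kekulé aromatic ring contributes 3 C=C     -> subtract 3 per ring
* a phosphoric monoester still carries P-OH    -> subtract ester from acid

These mirror how raw counts arrive from generic cheminformatics primitives
(ring perception, bond typing), keeping the raw counts inspectable and the
corrections auditable.  All corrected counts are floored at zero: fused
aromatics (naphthalene) and heteroaromatics (pyridine) legitimately yield
fewer Kekulé C=C bonds than 3 x rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from rdkit import Chem

from .chem_io import MoleculeRecord

__all__ = [
    "GroupDefinition",
    "FunctionalGroupCounts",
    "default_registry",
    "load_registry",
    "count_raw_groups",
    "apply_count_corrections",
    "count_groups",
    "NOT_COUNTED_GROUPS",
    "COUNTED_GROUPS",
]


class RegistryError(ValueError):
    """The group registry is inconsistent (bad SMARTS, missing field)."""


@dataclass(frozen=True)
class GroupDefinition:
    """One functional group: how it is counted and its contribution term."""

    group_id: str
    b: float
    method: str  # atom_count | ring_analysis | bond_analysis | substructure_pattern | not_counted
    k_index: Optional[int] = None
    smarts: Optional[str] = None
    precedence: Optional[int] = None
    source: str = ""
    raw_id: Optional[str] = None
    ignore_mask_from: tuple[str, ...] = ()

    def compiled(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts or "")
        if patt is None:
            raise RegistryError(
                f"SMARTS for group {self.group_id!r} failed to compile: {self.smarts!r}"
            )
        return patt


class FunctionalGroupCounts(dict):
    """Mapping group_id -> non-negative integer count (the v_k vector).

    Missing groups read as zero.
    """

    def __missing__(self, key: str) -> int:
        return 0

    def nonzero(self) -> dict[str, int]:
        return {k: v for k, v in self.items() if v}


def load_registry(source) -> list[GroupDefinition]:
    """Load a registry from a YAML mapping/stream (see ``data/groups.yaml``)."""
    data = yaml.safe_load(source) if not isinstance(source, dict) else source
    defs = []
    seen: set[str] = set()
    for entry in data["groups"]:
        gid = entry["id"]
        if gid in seen:
            raise RegistryError(f"duplicate group id {gid!r} in registry")
        seen.add(gid)
        if entry["method"] == "substructure_pattern" and "smarts" not in entry:
            raise RegistryError(f"group {gid!r} needs a SMARTS pattern")
        defs.append(
            GroupDefinition(
                group_id=gid,
                b=float(entry["b"]),
                method=entry["method"],
                k_index=entry.get("k"),
                smarts=entry.get("smarts"),
                precedence=entry.get("precedence"),
                source=entry.get("source", ""),
                raw_id=entry.get("raw_id"),
                ignore_mask_from=tuple(entry.get("ignore_mask_from", ())),
            )
        )
    return defs


@lru_cache(maxsize=1)
def _default_registry_cached() -> tuple[GroupDefinition, ...]:
    text = resources.files("volindex").joinpath("data/groups.yaml").read_text()
    return tuple(load_registry(text))


def default_registry() -> list[GroupDefinition]:
    """The registry shipped with the package (one entry per functional group)."""
    return list(_default_registry_cached())


def registry_b0(source=None) -> float:
    if source is None:
        text = resources.files("volindex").joinpath("data/groups.yaml").read_text()
        return float(yaml.safe_load(text)["b0"])
    return float(yaml.safe_load(source)["b0"])


#: Groups carried in the terms table but never counted (no reliable
#: automated detection method); their count is always zero.
NOT_COUNTED_GROUPS = frozenset(
    g.group_id for g in _default_registry_cached() if g.method == "not_counted"
)

#: The groups the counter produces (corrected keys).
COUNTED_GROUPS = tuple(
    g.group_id for g in _default_registry_cached() if g.method != "not_counted"
)


def _match_pattern_groups(
    mol: Chem.Mol, registry: Sequence[GroupDefinition]
) -> dict[str, list[frozenset[int]]]:
    """Match every substructure_pattern group in precedence order.

    Returns group_id -> list of matched atom-index sets.  Symmetry-duplicate
    matches are collapsed to unique atom sets; atoms consumed by a
    higher-precedence group block later matches except across the explicit
    ``ignore_mask_from`` pairs.
    """
    pattern_groups = sorted(
        (g for g in registry if g.method == "substructure_pattern"),
        key=lambda g: g.precedence if g.precedence is not None else 10**6,
    )
    consumed: dict[str, set[int]] = {}
    out: dict[str, list[frozenset[int]]] = {}
    for g in pattern_groups:
        blocked: set[int] = set()
        for other, atoms in consumed.items():
            if other not in g.ignore_mask_from:
                blocked |= atoms
        patt = g.compiled()
        seen: set[frozenset[int]] = set()
        taken: set[int] = set()
        hits: list[frozenset[int]] = []
        for m in mol.GetSubstructMatches(patt, uniquify=True):
            atoms = frozenset(m)
            if atoms in seen:
                continue
            seen.add(atoms)
            if atoms & (blocked | taken):
                continue
            hits.append(atoms)
            taken |= atoms
        consumed[g.group_id] = taken
        out[g.group_id] = hits
    return out


def _kekule_cc_double_bonds(mol: Chem.Mol) -> int:
    """Carbon-carbon double bonds under the Kekulé structure (aromatic
    bonds resolved to alternating single/double)."""
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    return sum(
        1
        for b in kek.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetBeginAtom().GetAtomicNum() == 6
        and b.GetEndAtom().GetAtomicNum() == 6
    )


def non_aromatic_cc_double_bonds(mol: Chem.Mol) -> int:
    """Direct count of non-aromatic C=C bonds (cross-check for the
    Kekulé-minus-3-per-aromatic-ring arithmetic)."""
    return sum(
        1
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE
        and not b.GetIsAromatic()
        and b.GetBeginAtom().GetAtomicNum() == 6
        and b.GetEndAtom().GetAtomicNum() == 6
    )


def count_raw_groups(
    mol: MoleculeRecord | Chem.Mol,
    registry: Optional[Sequence[GroupDefinition]] = None,
) -> FunctionalGroupCounts:
    """Raw (pre-correction) functional-group counts of a molecule.

    Carbon count is the number of carbon atoms; ring counts use SSSR (an
    aromatic ring is an SSSR ring all of whose bonds are aromatic); the raw
    C=C count is taken on the Kekulé structure so aromatic rings contribute
    three each, to be corrected afterwards.  SMARTS groups count unique
    atom-set matches under precedence masking.
    """
    rd = mol.mol if isinstance(mol, MoleculeRecord) else mol
    if rd is None:
        raise ValueError("no structure: record has no molecular graph")
    if registry is None:
        registry = default_registry()

    counts = FunctionalGroupCounts()
    counts["carbon"] = sum(1 for a in rd.GetAtoms() if a.GetAtomicNum() == 6)

    ring_info = rd.GetRingInfo()
    bond_rings = ring_info.BondRings()
    counts["ring_raw"] = len(bond_rings)
    counts["aromatic_ring"] = sum(
        1
        for ring in bond_rings
        if all(rd.GetBondWithIdx(i).GetIsAromatic() for i in ring)
    )
    counts["cdb_raw"] = _kekule_cc_double_bonds(rd)

    matches = _match_pattern_groups(rd, registry)
    for g in registry:
        if g.method == "substructure_pattern":
            key = g.raw_id or g.group_id
            counts[key] = len(matches[g.group_id])
        elif g.method == "not_counted":
            counts[g.group_id] = 0
    return counts


#: Correction rules: (corrected_key, raw_key, subtract_key, multiplier).
_CORRECTIONS = (
    ("non_aromatic_ring", "ring_raw", "aromatic_ring", 1),
    ("carbon_double_bond", "cdb_raw", "aromatic_ring", 3),
    ("hydroxyl", "hydroxyl_raw", "phenol", 1),
    ("phosphoric_acid", "phosphoric_acid_raw", "phosphoric_ester", 1),
)


def apply_count_corrections(raw: Mapping[str, int]) -> FunctionalGroupCounts:
    """Resolve the four known double-counting overlaps.

    Each rule subtracts one count from another (aromatic rings from rings,
    phenols from hydroxyls, 3 x aromatic rings from Kekulé C=C, phosphoric
    esters from phosphoric acids) and floors the result at zero.  Counts not
    involved in a rule pass through unchanged, and the operation is
    idempotent: corrected input (no ``*_raw`` keys left) is returned as-is.
    """
    out = FunctionalGroupCounts(raw)
    for corrected_key, raw_key, subtract_key, mult in _CORRECTIONS:
        if raw_key in out:
            raw_val = out.pop(raw_key)
            out[corrected_key] = max(raw_val - mult * out.get(subtract_key, 0), 0)
    return out


def count_groups(
    mol: MoleculeRecord | Chem.Mol,
    registry: Optional[Sequence[GroupDefinition]] = None,
) -> FunctionalGroupCounts:
    """Corrected functional-group counts: raw counting then correction rules."""
    return apply_count_corrections(count_raw_groups(mol, registry))
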