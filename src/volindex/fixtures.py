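"""Reference molecules with hand-enumerated group counts and volatility.

Every counted functional group appears in at least one molecule, together
with the edge cases that exercise the correction rules: fused aromatics
(naphthalene), heteroaromatics whose Kekulé structure has fewer than three
C=C per ring (pyridine, furan), sugar ring ethers (glucose), phenol vs
hydroxyl overlap (phenol, salicylic acid), phosphoric acid vs ester overlap
(methyl phosphate), and uncalculable stubs (generic R substituent,
undefined "n" repeat).

The expected values were produced by an independent arithmetic path —
manual enumeration of each structure's groups, correction rules applied by
hand, then log10 P = b0 + sum(v_k b_k) and the ideal-gas RVI conversion
computed directly from the printed terms — and are frozen here as the
oracle the pipeline is tested against.  :func:`compose_molecule` provides
the same two-path check for generated chain-plus-substituent molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .chem_io import MoleculeRecord, parse_molfile, parse_smiles
from .group_counting import default_registry, registry_b0
from .volatility import GAS_CONSTANT_L_ATM, STANDARD_TEMPERATURE_K

__all__ = ["FixtureCase", "builtin_fixture_suite", "compose_molecule"]


@dataclass
class FixtureCase:
    """One reference molecule and its hand-computed expected pipeline output."""

    name: str
    smiles: Optional[str] = None
    molblock: Optional[str] = None
    formula: str = ""
    mass: Optional[float] = None
    expected_counts: dict[str, int] = field(default_factory=dict)
    expected_log10p: Optional[float] = None
    expected_rvi: Optional[float] = None
    expected_category: Optional[str] = None
    uncalculable: bool = False
    uncalculable_reason: Optional[str] = None

    def make_record(self) -> MoleculeRecord:
        if self.molblock is not None:
            return parse_molfile(self.molblock, id=self.name, name=self.name)
        if self.smiles is not None:
            return parse_smiles(self.smiles, id=self.name, name=self.name)
        # formula-only stub (e.g. undefined repeat unit)
        return MoleculeRecord(
            id=self.name,
            name=self.name,
            formula=self.formula,
            mass=None,
            mol=None,
            has_repeat_n=self.uncalculable_reason == "n repeat",
        )


_R_STUB_MOLBLOCK = """R-stub (methyl ether with generic substituent, CH3OR)
  volindex

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    0.0000    0.0000 R   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
M  END
"""

# (name, smiles, formula, mass Da, corrected counts, log10P, RVI, category)
# — all expected values hand-enumerated and arithmetically frozen (see
# module docstring); RVI at T = 298.15 K with the package's weight table.
_CASES = [
    ("propane", "CCC", "C3H8", 44.0956, {"carbon": 3}, 0.4760, 9.7318, "high"),
    ("methylamine", "CN", "CH5N", 31.0571, {"carbon": 1, "amine_primary": 1}, 0.3220, 9.4256, "high"),
    ("benzene", "c1ccccc1", "C6H6", 78.1118, {"carbon": 6, "aromatic_ring": 1}, -1.5130, 7.9912, "high"),
    ("phenol", "Oc1ccccc1", "C6H6O", 94.1112, {"carbon": 6, "aromatic_ring": 1, "phenol": 1}, -3.6530, 5.9321, "high"),
    ("cyclohexane", "C1CCCCC1", "C6H12", 84.1595, {"carbon": 6, "non_aromatic_ring": 1}, -0.8484, 8.6882, "high"),
    ("ethanol", "CCO", "C2H6O", 46.0684, {"carbon": 2, "hydroxyl": 1}, -1.3160, 7.9589, "high"),
    ("acetic_acid", "CC(O)=O", "C2H4O2", 60.0520, {"carbon": 2, "carboxylic_acid": 1}, -2.6660, 6.7240, "high"),
    ("glycerol", "OCC(O)CO", "C3H8O3", 92.0938, {"carbon": 3, "hydroxyl": 3}, -6.2140, 3.3617, "high"),
    ("acetone", "CC(C)=O", "C3H6O", 58.0791, {"carbon": 3, "ketone": 1}, -0.4590, 8.9165, "high"),
    ("acetaldehyde", "CC=O", "C2H4O", 44.0526, {"carbon": 2, "aldehyde": 1}, -0.4360, 8.8194, "high"),
    ("ethyl_acetate", "CCOC(C)=O", "C4H8O2", 88.1051, {"carbon": 4, "ester": 1}, -1.1620, 8.3944, "high"),
    ("dimethyl_ether", "COC", "C2H6O", 46.0684, {"carbon": 2, "ether": 1}, 0.1960, 9.4709, "high"),
    ("diethyl_peroxide", "CCOOCC", "C4H10O2", 90.1210, {"carbon": 4, "peroxide": 1}, -0.3300, 9.2363, "high"),
    ("nitromethane", "C[N+](=O)[O-]", "CH3NO2", 61.0400, {"carbon": 1, "nitro": 1}, -0.7980, 8.5991, "high"),
    ("methyl_nitrate", "CO[N+](=O)[O-]", "CH3NO3", 77.0394, {"carbon": 1, "nitrate": 1}, -0.8780, 8.6202, "high"),
    ("acetamide", "CC(N)=O", "C2H5NO", 59.0672, {"carbon": 2, "amide": 1}, -1.3160, 8.0668, "high"),
    ("dimethylamine", "CNC", "C2H7N", 45.0837, {"carbon": 2, "amine_secondary": 1}, 0.0650, 9.3305, "high"),
    ("trimethylamine", "CN(C)C", "C3H9N", 59.1103, {"carbon": 3, "amine_tertiary": 1}, -0.1320, 9.2511, "high"),
    ("methanethiol", "CS", "CH4S", 48.1075, {"carbon": 1, "thiol": 1}, -0.8780, 8.4157, "high"),
    ("s_methyl_thioacetate", "CSC(C)=O", "C3H6OS", 90.1441, {"carbon": 3, "carbothioester": 1}, -0.7240, 8.8424, "high"),
    ("phosphoric_acid", "OP(O)(O)=O", "H3O4P", 97.9952, {"phosphoric_acid": 1}, -0.4400, 9.1627, "high"),
    ("trimethyl_phosphate", "COP(=O)(OC)OC", "C3H9O4P", 140.0749, {"carbon": 3, "phosphoric_ester": 1}, -1.7540, 8.0038, "high"),
    ("methyl_phosphate", "COP(O)(O)=O", "CH5O4P", 112.0218, {"carbon": 1, "phosphoric_ester": 1}, -0.8780, 8.7827, "high"),
    ("methyl_sulfate", "COS(=O)(=O)O", "CH4O4S", 112.1051, {"carbon": 1, "sulfate": 1}, -0.8780, 8.7831, "high"),
    ("methanesulfonic_acid", "CS(=O)(=O)O", "CH4O3S", 96.1057, {"carbon": 1, "sulfonate": 1}, -0.8780, 8.7162, "high"),
    ("toluene", "Cc1ccccc1", "C7H8", 92.1384, {"carbon": 7, "aromatic_ring": 1}, -1.9510, 7.6249, "high"),
    ("naphthalene", "c1ccc2ccccc2c1", "C10H8", 128.1705, {"carbon": 10, "aromatic_ring": 2}, -3.9400, 5.7792, "high"),
    ("tetrahydrofuran", "C1CCOC1", "C4H8O", 72.1057, {"carbon": 4, "ether": 1, "non_aromatic_ring": 1}, -0.6904, 8.7790, "high"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O", "C6H12O6", 180.1559, {"carbon": 6, "ether": 1, "non_aromatic_ring": 1, "hydroxyl": 5}, -12.7164, -2.8493, "nonvolatile"),
    ("salicylic_acid", "OC(=O)c1ccccc1O", "C7H6O3", 138.1207, {"carbon": 7, "aromatic_ring": 1, "carboxylic_acid": 1, "phenol": 1}, -7.6710, 2.0807, "high"),
    ("aniline", "Nc1ccccc1", "C6H7N", 93.1265, {"carbon": 6, "aromatic_ring": 1}, -1.5130, 8.0675, "high"),
    ("pyridine", "c1ccncc1", "C5H5N", 79.0999, {"carbon": 5, "aromatic_ring": 1}, -1.0750, 8.4346, "high"),
    ("isoprene", "C=C(C)C=C", "C5H8", 68.1170, {"carbon": 5, "carbon_double_bond": 2}, -0.6100, 8.8347, "high"),
    ("ethylene_glycol", "OCCO", "C2H6O2", 62.0678, {"carbon": 2, "hydroxyl": 2}, -3.5460, 5.8583, "high"),
    ("anisole", "COc1ccccc1", "C7H8O", 108.1378, {"carbon": 7, "aromatic_ring": 1, "ether": 1}, -2.6690, 6.9764, "high"),
    ("citric_acid", "OC(=O)CC(O)(CC(O)=O)C(O)=O", "C6H8O7", 192.1235, {"carbon": 6, "carboxylic_acid": 3, "hydroxyl": 1}, -13.8080, -3.9130, "nonvolatile"),
    ("tartaric_acid", "OC(C(O)C(O)=O)C(O)=O", "C4H6O6", 150.0868, {"carbon": 4, "carboxylic_acid": 2, "hydroxyl": 2}, -11.5820, -1.7942, "low"),
    ("malic_acid", "OC(CC(O)=O)C(O)=O", "C4H6O5", 134.0874, {"carbon": 4, "carboxylic_acid": 2, "hydroxyl": 1}, -9.3520, 0.3868, "moderate"),
]


def builtin_fixture_suite() -> list[FixtureCase]:
    """The shipped reference suite: 38 calculable molecules covering every
    counted group, plus two uncalculable stubs."""
    cases = [
        FixtureCase(
            name=name,
            smiles=smiles,
            formula=formula,
            mass=mass,
            expected_counts=dict(counts),
            expected_log10p=lp,
            expected_rvi=rvi,
            expected_category=cat,
        )
        for name, smiles, formula, mass, counts, lp, rvi, cat in _CASES
    ]
    cases.append(
        FixtureCase(
            name="r_group_stub",
            molblock=_R_STUB_MOLBLOCK,
            uncalculable=True,
            uncalculable_reason="R group",
        )
    )
    cases.append(
        FixtureCase(
            name="n_repeat_stub",
            formula="(C2H4O)n",
            uncalculable=True,
            uncalculable_reason="n repeat",
        )
    )
    return cases


# Substituent fragments attachable to a linear carbon chain: SMILES branch
# and the number of carbon atoms the fragment itself contributes.
_FRAGMENTS: dict[str, tuple[str, int]] = {
    "hydroxyl": ("(O)", 0),
    "thiol": ("(S)", 0),
    "amine_primary": ("(N)", 0),
    "amine_secondary": ("(NC)", 1),
    "amine_tertiary": ("(N(C)C)", 2),
    "carboxylic_acid": ("(C(O)=O)", 1),
    "amide": ("(C(N)=O)", 1),
    "aldehyde": ("(C=O)", 1),
    "ketone": ("(C(C)=O)", 2),
    "ester": ("(OC(C)=O)", 2),
    "ether": ("(OC)", 1),
    "peroxide": ("(OOC)", 1),
    "nitro": ("([N+](=O)[O-])", 0),
    "nitrate": ("(O[N+](=O)[O-])", 0),
    "sulfonate": ("(S(=O)(=O)O)", 0),
    "sulfate": ("(OS(=O)(=O)O)", 0),
    "carbothioester": ("(SC(C)=O)", 2),
}


def compose_molecule(
    base_chain_length: int, groups: Mapping[str, int] | None = None
) -> FixtureCase:
    """Assemble a linear-chain molecule carrying the requested substituents.

    One substituent is attached per chain carbon (first carbons first), so
    the chain must be at least as long as the total number of requested
    group occurrences.  The expected counts are the request itself plus the
    total carbon count (chain plus any carbons the fragments contribute —
    e.g. a carboxylic acid brings its own carbon); the expected log10 P is
    computed here by direct summation over the terms table, independently of
    the production pipeline, so the two paths can be cross-checked.
    """
    groups = dict(groups or {})
    if base_chain_length < 1:
        raise ValueError("chain length must be >= 1")
    unknown = sorted(set(groups) - set(_FRAGMENTS))
    if unknown:
        raise ValueError(
            f"cannot attach group(s) {', '.join(unknown)} to a linear chain"
        )
    attachments = [g for g, n in groups.items() for _ in range(n)]
    if len(attachments) > base_chain_length:
        raise ValueError(
            f"{len(attachments)} substituents do not fit on a "
            f"{base_chain_length}-carbon chain"
        )

    smiles_parts = []
    carbon_total = base_chain_length
    for i in range(base_chain_length):
        smiles_parts.append("C")
        if i < len(attachments):
            frag, extra_c = _FRAGMENTS[attachments[i]]
            smiles_parts.append(frag)
            carbon_total += extra_c
    smiles = "".join(smiles_parts)

    expected = {"carbon": carbon_total}
    for g, n in groups.items():
        if n:
            expected[g] = expected.get(g, 0) + n

    terms = {g.group_id: g.b for g in default_registry()}
    log10p = registry_b0() + sum(terms[g] * v for g, v in expected.items())

    name = "chain%d" % base_chain_length + "".join(
        f"_{g}{n}" for g, n in sorted(groups.items()) if n
    )
    rec = parse_smiles(smiles, id=name)
    rvi = None
    if rec.mass:
        import math

        rt = GAS_CONSTANT_L_ATM * STANDARD_TEMPERATURE_K
        rvi = log10p + math.log10(rec.mass / rt) + 9.0
    return FixtureCase(
        name=name,
        smiles=smiles,
        formula=rec.formula,
        mass=rec.mass,
        expected_counts=expected,
        expected_log10p=log10p,
        expected_rvi=rvi,
    )


def export_suite(directory: str | Path) -> tuple[Path, Path]:
    """Write the builtin suite as an SDF plus an expected-values CSV for
    cross-language reuse.  Returns the two paths."""
    from rdkit import Chem
    import csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sdf_path = directory / "fixture_suite.sdf"
    csv_path = directory / "fixture_expected.csv"

    cases = [c for c in builtin_fixture_suite() if c.smiles is not None]
    with open(sdf_path, "w") as fh:
        writer = Chem.SDWriter(fh)
        for c in cases:
            m = Chem.MolFromSmiles(c.smiles)
            m.SetProp("_Name", c.name)
            writer.write(m)
        writer.close()
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "smiles", "formula", "mass", "log10_p", "rvi", "category"])
        for c in cases:
            w.writerow(
                [c.name, c.smiles, c.formula, c.mass, c.expected_log10p, c.expected_rvi, c.expected_category]
            )
    return sdf_path, csv_path
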