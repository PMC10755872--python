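"""Reading molecular structures and computing molecular mass.

Structures enter the pipeline as MOL V2000 blocks, SDF files, or SMILES
strings and are normalised into :class:`MoleculeRecord` objects carrying an
RDKit molecule, a Hill-order formula, and the average molecular weight.

Mass is computed from the elemental formula with a fixed table of average
atomic weights (an older IUPAC revision; see :data:`DEFAULT_ATOMIC_WEIGHTS`)
chosen to reproduce database-style "molecular weight" values, e.g.
CH5N -> 31.0571 Da.  Structures that cannot be massed — undefined repeat
units ("n"), generic "R" substituents, pseudo-atoms — are flagged as
uncalculable rather than rejected, so batch runs degrade per-record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomicWeightTable",
    "DEFAULT_ATOMIC_WEIGHTS",
    "MoleculeRecord",
    "MolParseError",
    "FormulaError",
    "parse_formula",
    "molecular_weight",
    "parse_smiles",
    "parse_molfile",
    "read_sdf",
    "read_smiles_file",
    "fetch_kegg_mol",
]


class MolParseError(ValueError):
    """A structure block or SMILES string could not be parsed."""


class FormulaError(ValueError):
    """An elemental formula is malformed or uses an unknown element."""


#: Average atomic weights (Da).  Fixed to the older IUPAC single-value
#: revision (C 12.0107, H 1.00794, ...) because these reproduce KEGG-style
#: molecular weights to the printed fourth decimal; override per call if a
#: different revision is wanted.
DEFAULT_ATOMIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.00794,
    "B": 10.811,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 24.3050,
    "Si": 28.0855,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "K": 39.0983,
    "Ca": 40.078,
    "Mn": 54.938045,
    "Fe": 55.845,
    "Co": 58.933195,
    "Ni": 58.6934,
    "Cu": 63.546,
    "Zn": 65.38,
    "As": 74.92160,
    "Se": 78.96,
    "Br": 79.904,
    "Mo": 95.96,
    "I": 126.90447,
}

AtomicWeightTable = Mapping[str, float]

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

_KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)


@dataclass
class MoleculeRecord:
    """A parsed structure plus identity and calculability flags.

    ``mass`` is the average molecular weight in Da and is ``None`` whenever
    the record is uncalculable (R group, "n" repeat, or missing mass).
    """

    id: str
    name: str = ""
    formula: str = ""
    mass: Optional[float] = None
    mol: Optional[Chem.Mol] = field(default=None, repr=False)
    has_r_group: bool = False
    has_repeat_n: bool = False
    missing_mass: bool = False

    @property
    def is_calculable(self) -> bool:
        return (
            self.mol is not None
            and self.mass is not None
            and not self.has_r_group
            and not self.has_repeat_n
        )

    @property
    def uncalculable_reason(self) -> Optional[str]:
        if self.has_r_group:
            return "R group"
        if self.has_repeat_n:
            return "n repeat"
        if self.mass is None or self.missing_mass:
            return "missing mass"
        if self.mol is None:
            return "no structure"
        return None


def parse_formula(formula: str) -> tuple[dict[str, int], bool, bool]:
    """Expand an elemental formula into element counts.

    Handles Hill-order formulas with parenthesised repeats, e.g.
    ``C6H12O6`` or ``(C2H4O)3``.  Returns ``(counts, has_repeat_n,
    has_r_group)``; an undefined multiplier ``n`` (as in ``(C2H4O)nH2O``)
    or a generic ``R`` substituent sets the corresponding flag instead of
    raising.  Trailing charge markers (``+``/``-``) are ignored.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    has_n = False
    has_r = False

    # "R" is never an element here; flag and strip before tokenising.
    if re.search(r"R(?![a-z])", s):
        has_r = True
        s = re.sub(r"R(?![a-z])\d*", "", s)

    def scan(text: str, pos: int, depth: int) -> tuple[dict[str, int], int]:
        nonlocal has_n
        counts: dict[str, int] = {}
        while pos < len(text):
            ch = text[pos]
            if ch == "(":
                inner, pos = scan(text, pos + 1, depth + 1)
                mult_m = re.match(r"(\d+|n)", text[pos:])
                mult = 1
                if mult_m:
                    tok = mult_m.group(1)
                    pos += len(tok)
                    if tok == "n":
                        has_n = True
                        mult = 0
                    else:
                        mult = int(tok)
                for el, c in inner.items():
                    counts[el] = counts.get(el, 0) + c * mult
            elif ch == ")":
                if depth == 0:
                    raise FormulaError(f"unbalanced ')' in formula {formula!r}")
                return counts, pos + 1
            elif ch in "+-":
                pos += 1
                while pos < len(text) and text[pos].isdigit():
                    pos += 1
            elif ch == "n" and (pos + 1 == len(text) or not text[pos + 1].islower()):
                has_n = True
                pos += 1
            elif ch.isspace() or ch == ".":
                pos += 1
            else:
                m = _ELEMENT_RE.match(text, pos)
                if not m or m.start() != pos:
                    raise FormulaError(
                        f"cannot parse formula {formula!r} at position {pos}"
                    )
                el, num = m.group(1), m.group(2)
                # "C2H4On": a trailing repeat marker, not the element "On"
                if (
                    len(el) == 2
                    and el.endswith("n")
                    and not num
                    and el not in _KNOWN_ELEMENTS
                    and el[0] in _KNOWN_ELEMENTS
                ):
                    counts[el[0]] = counts.get(el[0], 0) + 1
                    has_n = True
                    pos = m.end()
                    continue
                counts[el] = counts.get(el, 0) + (int(num) if num else 1)
                pos = m.end()
        if depth != 0:
            raise FormulaError(f"unbalanced '(' in formula {formula!r}")
        return counts, pos

    counts, _ = scan(s, 0, 0)
    return counts, has_n, has_r


def molecular_weight(
    formula: str, table: AtomicWeightTable = DEFAULT_ATOMIC_WEIGHTS
) -> Optional[float]:
    """Average molecular weight (Da) of an elemental formula, to 4 decimals.

    Returns ``None`` — the uncalculable signal, not an exception — when the
    formula contains an undefined ``n`` repeat or a generic ``R`` group.
    Unknown elements raise :class:`FormulaError` naming the element.
    """
    counts, has_n, has_r = parse_formula(formula)
    if has_n or has_r:
        return None
    unknown = sorted(el for el in counts if el not in table)
    if unknown:
        raise FormulaError(
            f"unknown element(s) {', '.join(unknown)} in formula {formula!r}"
        )
    return round(sum(table[el] * n for el, n in counts.items()), 4)


def _finish_record(
    mol: Chem.Mol,
    id: str,
    name: str,
    has_r_group: bool,
    table: AtomicWeightTable,
) -> MoleculeRecord:
    formula = "" if has_r_group else rdMolDescriptors.CalcMolFormula(mol)
    mass = None
    has_n = False
    if formula:
        counts, has_n, has_r2 = parse_formula(formula)
        if not (has_n or has_r2):
            known = all(el in table for el in counts)
            if known:
                mass = molecular_weight(formula, table)
    return MoleculeRecord(
        id=id,
        name=name,
        formula=formula,
        mass=mass,
        mol=mol,
        has_r_group=has_r_group,
        has_repeat_n=has_n,
        missing_mass=mass is None and not has_r_group and not has_n,
    )


def parse_smiles(
    s: str, id: str = "", name: str = "", table: AtomicWeightTable = DEFAULT_ATOMIC_WEIGHTS
) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Aromaticity is perceived by RDKit's default model.  Dummy atoms (``*``)
    set the R-group flag and leave the mass absent.
    """
    if not s or not s.strip():
        raise MolParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise MolParseError(f"invalid SMILES {s!r}")
    has_r = any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())
    return _finish_record(mol, id or s, name, has_r, table)


def _check_v2000(text: str) -> None:
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolParseError("truncated MOL block: fewer than 4 header lines")
    counts_line = lines[3]
    if "V3000" in counts_line:
        raise MolParseError("MOL V3000 blocks are not supported; supply V2000")


def parse_molfile(
    text: str, id: str = "", name: str = "", table: AtomicWeightTable = DEFAULT_ATOMIC_WEIGHTS
) -> MoleculeRecord:
    """Parse a MOL V2000 block (or the first record of an SDF) into a record.

    Explicit hydrogens are folded into implicit counts.  Pseudo-atoms
    (``R``, ``R#``, ``*``) set ``has_r_group`` and leave the mass absent.
    Malformed input raises :class:`MolParseError` naming the offending line.
    """
    if not text or not text.strip():
        raise MolParseError("empty MOL block")
    block = text.split("$$$$")[0]
    _check_v2000(block)
    mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
    if mol is None:
        raise MolParseError(
            "malformed MOL block (atom/bond counts line or atom/bond block "
            "could not be read; see line 4 of the block)"
        )
    has_r = any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())
    if not has_r:
        try:
            Chem.SanitizeMol(mol)
            mol = Chem.RemoveHs(mol)
        except Exception as exc:  # valence/aromaticity perception failure
            raise MolParseError(f"MOL block failed sanitisation: {exc}") from exc
    if not name:
        name = block.splitlines()[0].strip()
    if not id:
        id = name
    return _finish_record(mol, id, name, has_r, table)


def read_sdf(
    text: str, table: AtomicWeightTable = DEFAULT_ATOMIC_WEIGHTS
) -> Iterator[MoleculeRecord]:
    """Iterate over the records of a multi-record SDF string."""
    for chunk in text.split("$$$$"):
        # each record after a "$$$$\n" separator starts with that newline;
        # drop it so the title line lands on line 1 of the block
        if chunk.startswith("\n"):
            chunk = chunk[1:]
        if not chunk.strip():
            continue
        yield parse_molfile(chunk, id="", name="", table=table)


def read_smiles_file(
    path: str | Path, table: AtomicWeightTable = DEFAULT_ATOMIC_WEIGHTS
) -> Iterator[MoleculeRecord]:
    """Read a plain-text SMILES list: one molecule per line, either
    ``SMILES`` or ``id<TAB>SMILES`` (a ``SMILES<TAB>id`` order is also
    accepted when the first field parses as SMILES and the second does not
    look like one)."""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            yield parse_smiles(parts[0], table=table)
        else:
            a, b = parts[0], parts[1]
            if Chem.MolFromSmiles(a) is not None and Chem.MolFromSmiles(b) is None:
                smiles, mol_id = a, b
            else:
                mol_id, smiles = a, b
            yield parse_smiles(smiles, id=mol_id, table=table)


_KEGG_URL = "https://rest.kegg.jp/get/{cid}/mol"


def fetch_kegg_mol(
    compound_id: str,
    cache_dir: str | Path | None = None,
    offline: bool = False,
) -> str:
    """Fetch the MOL block for a KEGG compound ID, with an on-disk cache.

    Network access is entirely optional: with ``offline=True`` (or when the
    network is unavailable) only the cache is consulted, and a cache miss
    raises ``FileNotFoundError``.  Nothing in the package requires this
    helper.
    """
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "volindex"
    cache.mkdir(parents=True, exist_ok=True)
    cached = cache / f"{compound_id}.mol"
    if cached.exists():
        return cached.read_text()
    if offline:
        raise FileNotFoundError(
            f"{compound_id} not in cache {cache} and offline mode is on"
        )
    from urllib.request import urlopen

    with urlopen(_KEGG_URL.format(cid=compound_id), timeout=30) as resp:
        text = resp.read().decode()
    cached.write_text(text)
    return text
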