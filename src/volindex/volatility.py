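"""Vapor pressure, relative volatility index (RVI), and categories.

The group-contribution model is

    log10 P = b0 + sum_k v_k * b_k          (P in atm)

with b0 = 1.79 and one additive term per functional-group occurrence (the
carbon term alone, b = -0.438, makes vapor pressure fall steeply with
molecular size).  Vapor pressure is converted to a saturation mass
concentration C* (ug m^-3) with the ideal gas law,

    RVI = log10 C* = log10 P + log10(M / (R T)) + 9

at T = 298.15 K, R = 0.0820574 L atm mol^-1 K^-1; the +9 converts g L^-1
to ug m^-3.  The RVI is environment-independent; category thresholds are
not.  In a clean atmosphere (about 1 ug m^-3 of condensed organics) the
low/moderate/high cut-points sit at log10 C* = -2, 0, +2; a polluted
atmosphere shifts them up by two decades, and soil — where only a small
fraction of the large organic-matter pool is available for partitioning —
can push the low and high cut-points to 4 and 8.

Gas-phase partitioning against a condensed organic pool C_total follows
the usual absorptive form xi = 1 / (1 + C*/C_total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .chem_io import MoleculeRecord
from .group_counting import (
    FunctionalGroupCounts,
    GroupDefinition,
    count_groups,
    default_registry,
    registry_b0,
)

__all__ = [
    "GAS_CONSTANT_L_ATM",
    "STANDARD_TEMPERATURE_K",
    "ContributionTable",
    "EnvironmentProfile",
    "CLEAN_ATMOSPHERE",
    "POLLUTED_ATMOSPHERE",
    "SOIL",
    "ENVIRONMENTS",
    "VolatilityEstimate",
    "log10_vapor_pressure",
    "rvi_from_log10p",
    "assign_category",
    "partition_fraction",
    "calc_vol",
]

GAS_CONSTANT_L_ATM = 0.0820574  # L atm mol^-1 K^-1
STANDARD_TEMPERATURE_K = 298.15

CATEGORIES = ("nonvolatile", "low", "moderate", "high")


class ContributionError(KeyError):
    """A counted group has no contribution term in the table."""


@dataclass(frozen=True)
class ContributionTable:
    """The constant b0 plus one contribution term b_k per group.

    Runtime-editable so the assumed terms (added by structural analogy for
    phosphorus/sulfur groups and amides) can be swapped for experimental
    values via :meth:`with_terms`.
    """

    b0: float = 1.79
    terms: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ContributionTable":
        return cls(
            b0=registry_b0(),
            terms={g.group_id: g.b for g in default_registry()},
        )

    def with_terms(self, **overrides: float) -> "ContributionTable":
        terms = dict(self.terms)
        terms.update(overrides)
        return ContributionTable(b0=self.b0, terms=terms)

    def __getitem__(self, group_id: str) -> float:
        try:
            return self.terms[group_id]
        except KeyError:
            raise ContributionError(
                f"no contribution term for group {group_id!r}"
            ) from None


@dataclass(frozen=True)
class EnvironmentProfile:
    """Named RVI category thresholds (log10 ug m^-3), low < moderate < high.

    ``c_total`` is the condensed-phase organic concentration (ug m^-3) used
    for partitioning calculations, when known for the environment.
    """

    name: str
    low_threshold: float
    moderate_threshold: float
    high_threshold: float
    c_total: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.low_threshold < self.moderate_threshold < self.high_threshold):
            raise ValueError(
                "thresholds must be strictly increasing: "
                f"{self.low_threshold}, {self.moderate_threshold}, {self.high_threshold}"
            )

    @classmethod
    def from_name(cls, name: str) -> "EnvironmentProfile":
        try:
            return ENVIRONMENTS[name]
        except KeyError:
            raise ValueError(
                f"unknown environment {name!r}; choose from {sorted(ENVIRONMENTS)}"
            ) from None


CLEAN_ATMOSPHERE = EnvironmentProfile("clean", -2.0, 0.0, 2.0, c_total=1.0)
#: Two decades more condensed organics than clean air shifts every cut-point up by 2.
POLLUTED_ATMOSPHERE = EnvironmentProfile("polluted", 0.0, 2.0, 4.0, c_total=100.0)
#: Upper-bound soil scenario (<0.1% of soil carbon available for partitioning).
SOIL = EnvironmentProfile("soil", 0.0, 4.0, 8.0)

ENVIRONMENTS = {e.name: e for e in (CLEAN_ATMOSPHERE, POLLUTED_ATMOSPHERE, SOIL)}


@dataclass
class VolatilityEstimate:
    """Result of the structure -> counts -> log10P -> RVI -> category pipeline."""

    id: str
    status: str  # "ok" | "uncalculable"
    log10_p: Optional[float] = None  # log10 atm
    rvi: Optional[float] = None  # log10 ug m^-3
    category: Optional[str] = None
    reason: Optional[str] = None
    counts: Optional[FunctionalGroupCounts] = None
    contributions: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def log10_vapor_pressure(
    counts: Mapping[str, int], table: Optional[ContributionTable] = None
) -> float:
    """log10 vapor pressure (atm): b0 plus the sum of v_k * b_k."""
    if table is None:
        table = ContributionTable.default()
    total = table.b0
    for group_id, v in counts.items():
        if v:
            total += v * table[group_id]
    return total


def rvi_from_log10p(log10_p: float, mass: float) -> float:
    """Relative volatility index: log10 C* in ug m^-3 at 298.15 K.

    ``mass`` is the average molecular weight in Da; the +9 converts the
    ideal-gas g L^-1 to ug m^-3.
    """
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    rt = GAS_CONSTANT_L_ATM * STANDARD_TEMPERATURE_K
    return log10_p + math.log10(mass / rt) + 9.0


def assign_category(rvi: float, env: EnvironmentProfile = CLEAN_ATMOSPHERE) -> str:
    """Bin an RVI into nonvolatile/low/moderate/high for an environment.

    A value exactly on a threshold goes to the upper bin.
    """
    if not math.isfinite(rvi):
        raise ValueError(f"RVI must be finite, got {rvi}")
    if rvi >= env.high_threshold:
        return "high"
    if rvi >= env.moderate_threshold:
        return "moderate"
    if rvi >= env.low_threshold:
        return "low"
    return "nonvolatile"


def partition_fraction(c_star: float, c_total: float) -> float:
    """Partitioning fraction xi = 1 / (1 + C*/C_total).

    Note the orientation: as written (and as commonly printed alongside this
    pipeline) the fraction *decreases* with C*, i.e. it is the fraction in
    the condensed phase for an absorptive-partitioning reading; the value is
    returned verbatim from this formula without reinterpretation.
    """
    if not c_total > 0:
        raise ValueError(f"c_total must be positive, got {c_total}")
    if c_star < 0:
        raise ValueError(f"c_star must be non-negative, got {c_star}")
    return 1.0 / (1.0 + c_star / c_total)


def calc_vol(
    mol: MoleculeRecord,
    table: Optional[ContributionTable] = None,
    env: EnvironmentProfile = CLEAN_ATMOSPHERE,
    registry: Optional[Sequence[GroupDefinition]] = None,
) -> VolatilityEstimate:
    """Full pipeline for one record; total over all inputs.

    Uncalculable records (generic R group, undefined "n" repeat, missing
    mass, no structure) come back with ``status="uncalculable"`` and a
    reason instead of raising.
    """
    if table is None:
        table = ContributionTable.default()
    reason = mol.uncalculable_reason
    if reason is not None:
        return VolatilityEstimate(id=mol.id, status="uncalculable", reason=reason)
    counts = count_groups(mol, registry)
    log10_p = log10_vapor_pressure(counts, table)
    rvi = rvi_from_log10p(log10_p, mol.mass)
    return VolatilityEstimate(
        id=mol.id,
        status="ok",
        log10_p=log10_p,
        rvi=rvi,
        category=assign_category(rvi, env),
        counts=counts,
        contributions={g: v * table[g] for g, v in counts.items() if v},
    )
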