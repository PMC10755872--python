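"""Batch volatility estimation and per-pathway summaries.

``calc_vol_batch`` turns a sequence of molecule records into a tidy pandas
DataFrame (one row per compound, uncalculable rows retained with their
reason); ``pathway_profile`` and ``category_distribution`` summarise such
tables the way pathway-level volatility screens report them: how many
compounds, what fraction could be calculated, the median RVI of those, and
the category histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chem_io import MoleculeRecord
from .group_counting import COUNTED_GROUPS, GroupDefinition
from .volatility import (
    CATEGORIES,
    CLEAN_ATMOSPHERE,
    ContributionTable,
    EnvironmentProfile,
    calc_vol,
)

__all__ = [
    "PathwayProfile",
    "calc_vol_batch",
    "pathway_profile",
    "profile_pathways",
    "category_distribution",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = (
    ["id", "name", "formula", "mass"]
    + list(COUNTED_GROUPS)
    + ["log10_p", "rvi", "category", "status", "reason"]
)


@dataclass
class PathwayProfile:
    """Volatility summary of one pathway's member compounds."""

    pathway_id: str
    n_total: int
    n_calculated: int
    pct_calculated: float
    median_rvi: Optional[float]
    category_counts: dict[str, int] = field(default_factory=dict)


def calc_vol_batch(
    mols: Iterable[MoleculeRecord],
    table: Optional[ContributionTable] = None,
    env: EnvironmentProfile = CLEAN_ATMOSPHERE,
    registry: Optional[Sequence[GroupDefinition]] = None,
) -> pd.DataFrame:
    """Run the pipeline over a compound collection.

    Returns one row per input in input order, with the corrected group
    counts, log10 P, RVI, category, and status columns of
    :data:`RESULT_COLUMNS`.  Uncalculable compounds keep their identity
    columns and a reason; their numeric columns are NaN.
    """
    if table is None:
        table = ContributionTable.default()
    rows = []
    for rec in mols:
        est = calc_vol(rec, table, env, registry)
        row: dict = {
            "id": rec.id,
            "name": rec.name,
            "formula": rec.formula,
            "mass": rec.mass,
        }
        counts = est.counts or {}
        for g in COUNTED_GROUPS:
            row[g] = counts.get(g, 0) if est.ok else pd.NA
        row.update(
            log10_p=est.log10_p,
            rvi=est.rvi,
            category=est.category,
            status=est.status,
            reason=est.reason,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def pathway_profile(pathway_id: str, rows: pd.DataFrame) -> PathwayProfile:
    """Summarise a batch-result table as one pathway's profile.

    The median RVI is taken over calculated compounds only (pandas median:
    mean of the middle two for even counts) and is absent when nothing was
    calculable.  ``pct_calculated`` uses the full member count as the
    denominator.
    """
    n_total = len(rows)
    ok = rows[rows["status"] == "ok"]
    n_calc = len(ok)
    cat_counts = {c: int((ok["category"] == c).sum()) for c in CATEGORIES}
    return PathwayProfile(
        pathway_id=pathway_id,
        n_total=n_total,
        n_calculated=n_calc,
        pct_calculated=100.0 * n_calc / n_total if n_total else 0.0,
        median_rvi=float(ok["rvi"].median()) if n_calc else None,
        category_counts=cat_counts,
    )


def profile_pathways(
    members: pd.DataFrame, results: pd.DataFrame
) -> pd.DataFrame:
    """Profile every pathway in a two-column membership table.

    ``members`` has columns ``pathway_id, compound_id``; ``results`` is a
    batch-result table keyed by ``id``.  Returns one summary row per
    pathway (members with no result row count toward ``n_total`` only).
    """
    out = []
    indexed = results.set_index("id")
    for pid, grp in members.groupby("pathway_id", sort=True):
        ids = grp["compound_id"].tolist()
        present = [i for i in ids if i in indexed.index]
        sub = indexed.loc[present].reset_index()
        prof = pathway_profile(str(pid), sub)
        prof.n_total = len(ids)
        prof.pct_calculated = (
            100.0 * prof.n_calculated / prof.n_total if prof.n_total else 0.0
        )
        row = {
            "pathway_id": prof.pathway_id,
            "n_total": prof.n_total,
            "n_calculated": prof.n_calculated,
            "pct_calculated": prof.pct_calculated,
            "median_rvi": prof.median_rvi,
        }
        row.update({f"n_{c}": prof.category_counts.get(c, 0) for c in CATEGORIES})
        out.append(row)
    return pd.DataFrame(out)


def category_distribution(rows: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per volatility category, over calculated rows.

    Percentages are relative to the number of compounds with an RVI (the
    calculable denominator); an empty result table yields an empty frame.
    """
    ok = rows[rows["status"] == "ok"]
    n = len(ok)
    if n == 0:
        return pd.DataFrame(columns=["category", "count", "percent"])
    recs = []
    for c in CATEGORIES:
        cnt = int((ok["category"] == c).sum())
        recs.append({"category": c, "count": cnt, "percent": 100.0 * cnt / n})
    return pd.DataFrame(recs)
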