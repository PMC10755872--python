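"""Agreement between automated estimates and a reference RVI table.

Automated pipelines of this kind are validated against manually computed
volatility databases using three agreement metrics: the fraction of
compounds with *identical* RVI (equal at 2-decimal reporting precision,
|delta| < 0.01), *similar* RVI (within 0.5 units, one quarter of a 2-unit
category bin), and the *same volatility category*.  Compounds uncalculable
on either side are excluded from the comparison and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .volatility import CLEAN_ATMOSPHERE, EnvironmentProfile, assign_category

__all__ = ["ComparisonSummary", "compare_to_reference"]


@dataclass
class ComparisonSummary:
    """Agreement counts/fractions plus the per-compound delta table."""

    n_compared: int
    n_identical: int
    n_within_half: int
    n_same_category: int
    n_excluded: int
    deltas: pd.DataFrame = field(repr=False, default=None)
    wilcoxon_p: Optional[float] = None

    @property
    def frac_identical(self) -> float:
        return self.n_identical / self.n_compared

    @property
    def frac_within_half(self) -> float:
        return self.n_within_half / self.n_compared

    @property
    def frac_same_category(self) -> float:
        return self.n_same_category / self.n_compared


def _check_unique(ids: pd.Series, label: str) -> None:
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate ids in {label} table: {dup}")


def compare_to_reference(
    auto: pd.DataFrame,
    ref: pd.DataFrame,
    env: EnvironmentProfile = CLEAN_ATMOSPHERE,
    identical_tol: float = 0.01,
) -> ComparisonSummary:
    """Compare a batch-result table against a reference ``{id, rvi[, category]}``.

    Deltas are ``auto.rvi - ref.rvi`` over the id join.  Reference rows
    without a category get one recomputed from their RVI under ``env``.
    Compounds missing an RVI on either side are excluded from
    ``n_compared`` and tallied in ``n_excluded``.  A paired Wilcoxon
    signed-rank test on the RVI pairs is reported as supplementary output
    (NaN when every delta is zero).
    """
    _check_unique(auto["id"], "auto")
    _check_unique(ref["id"], "reference")

    a = auto[["id", "rvi"]].copy()
    if "category" in auto.columns:
        a["category"] = auto["category"]
    if "status" in auto.columns:
        a.loc[auto["status"] != "ok", "rvi"] = np.nan
    r = ref[["id", "rvi"]].rename(columns={"rvi": "rvi_ref"})
    if "category" in ref.columns:
        r["category_ref"] = ref["category"]

    merged = a.merge(r, on="id", how="inner")
    if merged.empty:
        raise ValueError("no shared ids between auto and reference tables")

    usable = merged.dropna(subset=["rvi", "rvi_ref"]).copy()
    n_excluded = len(merged) - len(usable)
    if usable.empty:
        raise ValueError("no compound calculable on both sides")

    if "category" not in usable.columns or usable["category"].isna().any():
        usable["category"] = [assign_category(v, env) for v in usable["rvi"]]
    if "category_ref" not in usable.columns:
        usable["category_ref"] = [assign_category(v, env) for v in usable["rvi_ref"]]
    else:
        missing = usable["category_ref"].isna()
        usable.loc[missing, "category_ref"] = [
            assign_category(v, env) for v in usable.loc[missing, "rvi_ref"]
        ]

    usable["delta"] = usable["rvi"] - usable["rvi_ref"]
    usable["same_category"] = usable["category"] == usable["category_ref"]

    n = len(usable)
    n_identical = int((usable["delta"].abs() < identical_tol).sum())
    n_within = int((usable["delta"].abs() <= 0.5).sum())
    n_same = int(usable["same_category"].sum())

    if (usable["delta"] == 0).all():
        p = float("nan")
    else:
        p = float(stats.wilcoxon(usable["rvi"], usable["rvi_ref"]).pvalue)

    return ComparisonSummary(
        n_compared=n,
        n_identical=n_identical,
        n_within_half=n_within,
        n_same_category=n_same,
        n_excluded=n_excluded,
        deltas=usable[
            ["id", "rvi", "rvi_ref", "delta", "category", "category_ref", "same_category"]
        ].reset_index(drop=True),
        wilcoxon_p=p,
    )
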