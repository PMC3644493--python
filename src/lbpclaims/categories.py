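"""Cherkin classification of mechanical low-back ICD-9 codes.

Maps 4-digit ICD-9 codes to the seven clinical categories of mechanical
low back problems (Cherkin et al.) and builds year-over-year frequency
tables: per-category claim counts, shares of all classified claims, and
three change measures between two comparison years.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "CHERKIN_CATEGORIES",
    "UNCLASSIFIED",
    "classify",
    "classify_series",
    "category_table",
]

UNCLASSIFIED = "Unclassified"

#: Category -> 4-digit ICD-9 codes.  The seven sets are pairwise disjoint.
CHERKIN_CATEGORIES: Dict[str, frozenset[str]] = {
    "Herniated disc": frozenset({"7221", "7222", "7227"}),
    "Probably degenerative changes": frozenset(
        {"7213", "7215", "7216", "7217", "7218", "7219", "7225", "7226", "7229"}
    ),
    "Spinal stenosis": frozenset({"7214", "7240"}),
    "Possible instability": frozenset({"7246"}),
    "Non-specific back aches": frozenset({"7242", "7245"}),
    "Sequelae of previous back surgery": frozenset({"7228"}),
    "Miscellaneous": frozenset(
        {"7223", "7243", "7244", "7248", "7249", "7393", "7394"}
    ),
}

CATEGORY_ORDER = list(CHERKIN_CATEGORIES)

_CODE_TO_CATEGORY: Dict[str, str] = {
    code: cat for cat, codes in CHERKIN_CATEGORIES.items() for code in codes
}


def classify(code: str) -> str:
    """Category of one 4-digit ICD-9 code; total via :data:`UNCLASSIFIED`."""
    return _CODE_TO_CATEGORY.get(str(code), UNCLASSIFIED)


def classify_series(codes: pd.Series) -> pd.Series:
    """Vectorised :func:`classify`."""
    return codes.astype(str).map(_CODE_TO_CATEGORY).fillna(UNCLASSIFIED)


def category_table(
    claims: pd.DataFrame,
    year_a: int,
    year_b: int,
    *,
    cases: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Cherkin-category frequency comparison between two years.

    Parameters
    ----------
    claims
        LBP claims of the selected case patients.  All their claims in each
        comparison calendar year enter the table, not just witness triples.
    year_a, year_b
        Comparison years (earlier, later).
    cases
        Optional case assignments (columns patient_id, index_year): when
        given, year-Y claims are restricted to patients who are cases in Y.

    Returns
    -------
    DataFrame indexed by category with columns ``n_a``, ``n_b``,
    ``share_a``, ``share_b`` (percent of classified claims),
    ``delta_n`` (count change), ``share_point_change`` (percentage points)
    and ``pct_change_within`` (percent change of the category's own count,
    earlier year as denominator; NaN when the earlier count is zero).

    Raises
    ------
    ValueError
        If either year contributes zero classified claims (shares would be
        undefined).
    """
    df = claims.copy()
    df["year"] = pd.to_datetime(df["service_date"]).dt.year
    df["category"] = classify_series(df["icd9"])
    df = df[df["category"] != UNCLASSIFIED]

    counts = {}
    for year in (year_a, year_b):
        sub = df[df["year"] == year]
        if cases is not None:
            in_year = set(
                cases.loc[cases["index_year"] == year, "patient_id"].astype(str)
            )
            sub = sub[sub["patient_id"].astype(str).isin(in_year)]
        c = sub.groupby("category").size()
        if int(c.sum()) == 0:
            raise ValueError(f"no classified claims in year {year}; shares undefined")
        counts[year] = c.reindex(CATEGORY_ORDER, fill_value=0)

    n_a, n_b = counts[year_a], counts[year_b]
    share_a = 100.0 * n_a / n_a.sum()
    share_b = 100.0 * n_b / n_b.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_within = 100.0 * (n_b - n_a) / n_a.replace(0, np.nan)
    table = pd.DataFrame(
        {
            "n_a": n_a,
            "n_b": n_b,
            "share_a": share_a,
            "share_b": share_b,
            "delta_n": n_b - n_a,
            "share_point_change": share_b - share_a,
            "pct_change_within": pct_within,
        }
    )
    table.index.name = "category"
    return table


def table_from_counts(
    counts_a: Dict[str, int], counts_b: Dict[str, int]
) -> pd.DataFrame:
    """Build the comparison table directly from per-category counts.

    Convenience for recomputing change columns from published count
    columns; same output layout as :func:`category_table`.
    """
    n_a = pd.Series(counts_a).reindex(CATEGORY_ORDER, fill_value=0)
    n_b = pd.Series(counts_b).reindex(CATEGORY_ORDER, fill_value=0)
    if n_a.sum() == 0 or n_b.sum() == 0:
        raise ValueError("zero total claims; shares undefined")
    share_a = 100.0 * n_a / n_a.sum()
    share_b = 100.0 * n_b / n_b.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_within = 100.0 * (n_b - n_a) / n_a.replace(0, np.nan)
    table = pd.DataFrame(
        {
            "n_a": n_a,
            "n_b": n_b,
            "share_a": share_a,
            "share_b": share_b,
            "delta_n": n_b - n_a,
            "share_point_change": share_b - share_a,
            "pct_change_within": pct_within,
        }
    )
    table.index.name = "category"
    return table


__all__.append("table_from_counts")
__all__.append("CATEGORY_ORDER")
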