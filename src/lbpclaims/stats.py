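"""Surveillance statistics: prevalence, intervals, risk ratios, trends.

All intervals share one confidence level (default 99%).  Binomial
proportions get Wilson score intervals — asymmetric, boundary-respecting,
the standard choice for surveillance proportions far from 0.5/n.  Risk
ratios get the Katz log-normal interval.  Trends are ordinary least
squares of annual prevalence (percent) on calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .config import StudyConfig, band_labels

__all__ = [
    "PrevalenceEstimate",
    "RiskRatio",
    "TrendSummary",
    "wilson_interval",
    "prevalence",
    "relative_risk",
    "percent_variation",
    "trend_slope",
    "report_tables",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    year: int
    sex: str
    age_band: str
    cases: int
    denominator: int
    point: float  # percent
    lower: float  # percent
    upper: float  # percent


@dataclass(frozen=True)
class RiskRatio:
    rr: float
    lower: float
    upper: float


@dataclass(frozen=True)
class TrendSummary:
    sex: str
    age_band: str
    slope: float  # prevalence percent per year
    percent_variation: float  # endpoint-to-endpoint, percent


def wilson_interval(k, n, confidence: float = 0.99):
    """Wilson score interval for a binomial proportion.

    Inverts the score test: the interval around
    ``(p̂ + z²/2n) / (1 + z²/n)`` with half-width
    ``z·sqrt(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n)``, clipped to [0, 1].

    Accepts scalars or arrays; returns (lower, upper) proportions.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(n_arr <= 0):
        raise ValueError("wilson_interval undefined for n = 0")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    lo, hi = proportion_confint(k_arr, n_arr, alpha=1.0 - confidence, method="wilson")
    # boundary cases are exact in the score inversion; keep them exact here
    lo = np.where(k_arr == 0, 0.0, np.clip(lo, 0.0, 1.0))
    hi = np.where(k_arr == n_arr, 1.0, np.clip(hi, 0.0, 1.0))
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(lo), float(hi)
    return lo, hi


def prevalence(
    case_counts: pd.DataFrame,
    denominators: pd.DataFrame,
    confidence: float = 0.99,
) -> pd.DataFrame:
    """Stratified annual prevalence with Wilson intervals.

    Parameters
    ----------
    case_counts
        Columns ``year, sex, age_band, cases`` (output of
        :func:`lbpclaims.phenotype.phenotype_population`).  Strata present
        in the denominators but absent here count zero cases.
    denominators
        Columns ``year, sex, age_band, count``; every case stratum must
        have a match.
    confidence
        Interval confidence level.

    Returns
    -------
    DataFrame with columns year, sex, age_band, cases, denominator,
    point, lower, upper (percent).  Zero-denominator strata are emitted as
    explicit rows with NaN point/bounds, never silently dropped.
    """
    denom = denominators.rename(columns={"count": "denominator"})
    merged = denom.merge(case_counts, on=["year", "sex", "age_band"], how="outer")
    orphan = merged["denominator"].isna()
    if orphan.any():
        row = merged.loc[orphan].iloc[0]
        raise ValueError(
            "no denominator for stratum "
            f"(year={int(row['year'])}, sex={row['sex']}, age_band={row['age_band']})"
        )
    merged["cases"] = merged["cases"].fillna(0).astype(int)
    merged["denominator"] = merged["denominator"].astype(int)

    pos = merged["denominator"] > 0
    point = np.full(len(merged), np.nan)
    lower = np.full(len(merged), np.nan)
    upper = np.full(len(merged), np.nan)
    if pos.any():
        k = merged.loc[pos, "cases"].to_numpy()
        n = merged.loc[pos, "denominator"].to_numpy()
        lo, hi = wilson_interval(k, n, confidence)
        point[pos.to_numpy()] = 100.0 * k / n
        lower[pos.to_numpy()] = 100.0 * np.asarray(lo)
        upper[pos.to_numpy()] = 100.0 * np.asarray(hi)
    merged["point"] = point
    merged["lower"] = lower
    merged["upper"] = upper
    return (
        merged.loc[
            :,
            ["year", "sex", "age_band", "cases", "denominator", "point", "lower", "upper"],
        ]
        .sort_values(["year", "sex", "age_band"])
        .reset_index(drop=True)
    )


def relative_risk(
    k1: int, n1: int, k0: int, n0: int, confidence: float = 0.99
) -> RiskRatio:
    """Risk ratio (k1/n1)/(k0/n0) with the Katz log-normal interval.

    ``exp(ln rr ± z·sqrt(1/k1 − 1/n1 + 1/k0 − 1/n0))``.  Both event counts
    must be positive for the interval to exist.
    """
    if min(n1, n0) <= 0:
        raise ValueError("denominators must be positive")
    if k1 <= 0 or k0 <= 0:
        raise ValueError(
            "relative-risk interval undefined when either event count is zero"
        )
    rr = (k1 / n1) / (k0 / n0)
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    se = np.sqrt(1.0 / k1 - 1.0 / n1 + 1.0 / k0 - 1.0 / n0)
    return RiskRatio(
        rr=float(rr),
        lower=float(rr * np.exp(-z * se)),
        upper=float(rr * np.exp(z * se)),
    )


def percent_variation(first: float, last: float) -> float:
    """Endpoint-to-endpoint percent change, 100·(last − first)/first.

    Returned unrounded; reports round to the nearest integer.
    """
    if first == 0:
        raise ValueError("percent variation undefined for a zero baseline")
    return 100.0 * (last - first) / first


def trend_slope(yearly_points: Sequence[tuple[int, float]]) -> float:
    """OLS slope of annual prevalence (percent) on calendar year."""
    pts = list(yearly_points)
    if len(pts) < 2:
        raise ValueError("trend_slope needs at least two yearly points")
    years = np.asarray([p[0] for p in pts], dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("trend_slope needs at least two distinct years")
    values = np.asarray([p[1] for p in pts], dtype=float)
    return float(sps.linregress(years, values).slope)


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if np.isfinite(x) else 0


def report_tables(
    case_counts: pd.DataFrame,
    denominators: pd.DataFrame,
    config: StudyConfig,
    claims: Optional[pd.DataFrame] = None,
    cases: Optional[pd.DataFrame] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict[str, pd.DataFrame]:
    """Produce the three publication-style surveillance tables.

    * ``prevalence`` — per (sex, band): endpoint-year prevalences with
      Wilson CIs, integer percent variation, OLS slope over all study
      years with data.
    * ``relative_risk`` — per (band, endpoint year): male:female risk
      ratio with Katz CI (rows with a zero event count are emitted with
      NaN values rather than dropped).
    * ``categories`` — Cherkin comparison of the two endpoint years,
      present only when ``claims`` (and optionally ``cases``) are given.

    With ``out_dir`` set, each table is also written as
    ``table_<name>.csv``.  Rounding follows the printed precision:
    prevalence and RR to 2 decimals, slopes to 3, percent variation to
    integers.
    """
    from .categories import category_table  # local import avoids cycle

    conf = config.confidence
    prev = prevalence(case_counts, denominators, conf)
    year_a, year_b = config.study_years

    rows = []
    for (sex, band), grp in prev.groupby(["sex", "age_band"], sort=True):
        series = grp.dropna(subset=["point"]).sort_values("year")
        by_year = {int(r.year): r for r in series.itertuples()}
        ra, rb = by_year.get(year_a), by_year.get(year_b)
        var = (
            _round_half_away(percent_variation(ra.point, rb.point))
            if ra is not None and rb is not None and ra.point > 0
            else np.nan
        )
        slope = (
            trend_slope(list(zip(series["year"], series["point"])))
            if len(series) >= 2
            else np.nan
        )
        rows.append(
            {
                "sex": sex,
                "age_band": band,
                f"prev_{year_a}": round(ra.point, 2) if ra is not None else np.nan,
                f"lower_{year_a}": round(ra.lower, 2) if ra is not None else np.nan,
                f"upper_{year_a}": round(ra.upper, 2) if ra is not None else np.nan,
                f"prev_{year_b}": round(rb.point, 2) if rb is not None else np.nan,
                f"lower_{year_b}": round(rb.lower, 2) if rb is not None else np.nan,
                f"upper_{year_b}": round(rb.upper, 2) if rb is not None else np.nan,
                "pct_var": var,
                "slope": round(slope, 3) if np.isfinite(slope) else np.nan,
            }
        )
    band_order = {b: i for i, b in enumerate(band_labels(config.bands))}
    table1 = (
        pd.DataFrame(rows)
        .sort_values(["age_band", "sex"], key=lambda s: s.map(band_order).fillna(s))
        .reset_index(drop=True)
        if rows
        else pd.DataFrame()
    )

    rr_rows = []
    strata = prev.set_index(["year", "sex", "age_band"])
    for year in (year_a, year_b):
        for band in band_labels(config.bands):
            try:
                m = strata.loc[(year, "male", band)]
                f = strata.loc[(year, "female", band)]
            except KeyError:
                continue
            row = {"age_band": band, "year": year}
            if m["cases"] > 0 and f["cases"] > 0 and min(m["denominator"], f["denominator"]) > 0:
                rr = relative_risk(
                    int(m["cases"]), int(m["denominator"]),
                    int(f["cases"]), int(f["denominator"]), conf,
                )
                row.update(
                    rr=round(rr.rr, 2), lower=round(rr.lower, 2), upper=round(rr.upper, 2)
                )
            else:
                row.update(rr=np.nan, lower=np.nan, upper=np.nan)
            rr_rows.append(row)
    table2 = pd.DataFrame(
        rr_rows, columns=["age_band", "year", "rr", "lower", "upper"]
    )

    tables = {"prevalence": table1, "relative_risk": table2}
    if claims is not None:
        try:
            cat = category_table(claims, year_a, year_b, cases=cases)
        except ValueError:
            cat = pd.DataFrame()
        tables["categories"] = cat

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            tbl.to_csv(out / f"table_{name}.csv", index=name == "categories")
    return tables


def aggregate_prevalence(
    case_counts: pd.DataFrame,
    denominators: pd.DataFrame,
    confidence: float = 0.99,
) -> pd.DataFrame:
    """Annual all-adult prevalence per sex, aggregating bands before division.

    Cases and denominators are summed over age bands within (year, sex) and
    divided once — never an average of band-level rates.
    """
    cases = case_counts.groupby(["year", "sex"], as_index=False)["cases"].sum()
    denom = denominators.groupby(["year", "sex"], as_index=False)["count"].sum()
    counts = cases.rename(columns={"cases": "cases"})
    counts["age_band"] = "all"
    denom["age_band"] = "all"
    return prevalence(counts, denom, confidence).drop(columns="age_band")


__all__.append("aggregate_prevalence")
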