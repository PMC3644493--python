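"""The recurrence phenotype: claims-based recurrent low back pain.

A patient is a case for index year Y when at least ``min_claims`` diagnoses
with identical ICD-9 stem fall within one ``window_days``-day period and at
least one of those diagnoses is dated in Y.  The scan is linear after
sorting: per (patient, stem), slide a window of ``min_claims`` consecutive
distinct service dates; every window whose span fits marks each study year
it touches.  Any qualifying set of dates contains such a consecutive
window, so the sliding scan is equivalent to enumerating all date triples.

Two notions of "a 365-day period" are supported: the default counts a
window whose last and first date differ by strictly less than 365 days
(the period includes both endpoints); ``span_inclusive`` relaxes this to
``<= 365`` for sensitivity analysis.  Same-day repeat billings collapse to
one diagnosis occurrence unless ``distinct_dates`` is switched off.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .config import StudyConfig, band_of

__all__ = [
    "CaseAssignment",
    "DataIntegrityError",
    "find_case_years",
    "phenotype_population",
]


class DataIntegrityError(ValueError):
    """A patient carries inconsistent sex or birth year across claims."""


@dataclass(frozen=True)
class CaseAssignment:
    """One patient flagged as a case for one index year.

    ``witness_dates`` are the service dates of the earliest qualifying
    window covering the year (ties broken by stem); they share
    ``qualifying_stem`` and span less than the configured window.
    """

    patient_id: str
    index_year: int
    qualifying_stem: str
    witness_dates: tuple[dt.date, ...]

    @property
    def first_witness_date(self) -> dt.date:
        return self.witness_dates[0]


def _as_day_items(
    claims: Union[pd.DataFrame, Iterable[tuple]], config: StudyConfig
) -> list[tuple[str, dt.date]]:
    """Normalise one patient's claims to (identity-key, date) pairs."""
    if isinstance(claims, pd.DataFrame):
        codes = claims["icd9"].astype(str)
        dates = pd.to_datetime(claims["service_date"])
        pairs = list(zip(codes, dates.dt.date))
    else:
        pairs = [(str(c), pd.Timestamp(d).date()) for d, c in claims]
    key = (lambda c: c[:3]) if config.stem_identity else (lambda c: c)
    return [(key(c), d) for c, d in pairs]


def find_case_years(
    claims: Union[pd.DataFrame, Iterable[tuple]],
    config: StudyConfig,
) -> Dict[int, CaseAssignment]:
    """Index years for which one patient's claims qualify.

    Parameters
    ----------
    claims
        The patient's LBP claims: a claims frame or an iterable of
        (service_date, icd9) pairs.  Dates are assumed pre-filtered to the
        extraction window.
    config
        Recurrence rule parameters.

    Returns
    -------
    dict
        ``{index_year: CaseAssignment}`` for every qualifying study year;
        empty input gives an empty dict.
    """
    items = _as_day_items(claims, config)
    if not items:
        return {}
    patient_id = ""
    if isinstance(claims, pd.DataFrame) and len(claims):
        patient_id = str(claims["patient_id"].iloc[0]) if "patient_id" in claims else ""

    by_key: Dict[str, list[dt.date]] = {}
    for key, day in items:
        by_key.setdefault(key, []).append(day)

    k = config.min_claims
    limit = config.window_days if config.span_inclusive else config.window_days - 1
    first_year, last_year = config.study_years
    found: Dict[int, CaseAssignment] = {}

    for key in sorted(by_key):
        days = sorted(set(by_key[key])) if config.distinct_dates else sorted(by_key[key])
        for i in range(len(days) - k + 1):
            window = days[i : i + k]
            if (window[-1] - window[0]).days > limit:
                continue
            for day in window:
                y = day.year
                if not (first_year <= y <= last_year):
                    continue
                cand = CaseAssignment(patient_id, y, key, tuple(window))
                prev = found.get(y)
                if prev is None or (window[0], key) < (
                    prev.witness_dates[0],
                    prev.qualifying_stem,
                ):
                    found[y] = cand
    return found


def _year_of_days(days: np.ndarray) -> np.ndarray:
    """Calendar year of int64 day-since-epoch values."""
    return days.astype("datetime64[D]").astype("datetime64[Y]").astype(np.int64) + 1970


def phenotype_population(
    claims: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the recurrence phenotype to a whole claims extract.

    Vectorised equivalent of grouping by patient and calling
    :func:`find_case_years`; linear in the number of claims after one sort.
    Case-years are only assigned when the patient's mid-year age at the
    index year reaches ``config.min_age``.

    Returns
    -------
    (assignments, counts)
        ``assignments`` has one row per (patient, index year):
        patient_id, index_year, sex, age_band, qualifying_stem,
        first_witness_date.  ``counts`` aggregates cases per
        (year, sex, age_band).

    Raises
    ------
    DataIntegrityError
        If any patient has more than one recorded sex or birth year.
    """
    empty_assign = pd.DataFrame(
        columns=[
            "patient_id",
            "index_year",
            "sex",
            "age_band",
            "qualifying_stem",
            "first_witness_date",
        ]
    )
    empty_counts = pd.DataFrame(columns=["year", "sex", "age_band", "cases"])
    if claims.empty:
        return empty_assign, empty_counts

    demo = claims[["patient_id", "sex", "birth_year"]].drop_duplicates()
    dup = demo["patient_id"].duplicated()
    if dup.any():
        bad = demo.loc[dup, "patient_id"].iloc[0]
        raise DataIntegrityError(
            f"patient {bad!r} has inconsistent sex/birth_year across claims"
        )

    key = (
        claims["icd9"].astype(str).str[:3]
        if config.stem_identity
        else claims["icd9"].astype(str)
    )
    pat_u, p = np.unique(claims["patient_id"].to_numpy(), return_inverse=True)
    stem_u, s = np.unique(key.to_numpy(), return_inverse=True)
    d = (
        pd.to_datetime(claims["service_date"])
        .to_numpy()
        .astype("datetime64[D]")
        .astype(np.int64)
    )

    order = np.lexsort((d, s, p))
    p, s, d = p[order], s[order], d[order]
    if config.distinct_dates:
        keep = np.ones(len(p), dtype=bool)
        keep[1:] = (p[1:] != p[:-1]) | (s[1:] != s[:-1]) | (d[1:] != d[:-1])
        p, s, d = p[keep], s[keep], d[keep]

    k = config.min_claims
    if len(p) < k:
        return empty_assign, empty_counts
    limit = config.window_days if config.span_inclusive else config.window_days - 1

    same = (p[k - 1 :] == p[: len(p) - k + 1]) & (s[k - 1 :] == s[: len(s) - k + 1])
    span = d[k - 1 :] - d[: len(d) - k + 1]
    starts = np.nonzero(same & (span <= limit))[0]
    if len(starts) == 0:
        return empty_assign, empty_counts

    # explode each qualifying window into (patient, year, window) candidates
    cand_start = np.repeat(starts, k)
    member = cand_start + np.tile(np.arange(k), len(starts))
    cand_year = _year_of_days(d[member])
    cand_pat = p[cand_start]

    first_year, last_year = config.study_years
    in_study = (cand_year >= first_year) & (cand_year <= last_year)

    birth = np.empty(len(pat_u), dtype=np.int64)
    birth[np.searchsorted(pat_u, demo["patient_id"].to_numpy())] = demo[
        "birth_year"
    ].to_numpy()
    of_age = (cand_year - birth[cand_pat]) >= config.min_age
    mask = in_study & of_age
    if not mask.any():
        return empty_assign, empty_counts
    cand_start, cand_year, cand_pat = cand_start[mask], cand_year[mask], cand_pat[mask]

    # earliest window per (patient, year); ties broken by stem label order
    sel = np.lexsort((s[cand_start], d[cand_start], cand_year, cand_pat))
    cand_start, cand_year, cand_pat = cand_start[sel], cand_year[sel], cand_pat[sel]
    first = np.ones(len(cand_pat), dtype=bool)
    first[1:] = (cand_pat[1:] != cand_pat[:-1]) | (cand_year[1:] != cand_year[:-1])
    win, year, pat = cand_start[first], cand_year[first], cand_pat[first]

    age = year - birth[pat]
    edges = np.array([b.lo for b in config.bands], dtype=np.int64)
    labels = np.array([b.label for b in config.bands])
    band_idx = np.searchsorted(edges, age, side="right") - 1

    sex_per_pat = np.empty(len(pat_u), dtype=object)
    sex_per_pat[np.searchsorted(pat_u, demo["patient_id"].to_numpy())] = demo[
        "sex"
    ].to_numpy()

    assignments = pd.DataFrame(
        {
            "patient_id": pat_u[pat],
            "index_year": year,
            "sex": sex_per_pat[pat],
            "age_band": labels[band_idx],
            "qualifying_stem": stem_u[s[win]]
            if config.stem_identity
            else [c[:3] for c in stem_u[s[win]]],
            "first_witness_date": d[win].astype("datetime64[D]"),
        }
    )
    assignments = assignments.sort_values(["patient_id", "index_year"]).reset_index(
        drop=True
    )

    counts = (
        assignments.groupby(["index_year", "sex", "age_band"], observed=True)
        .size()
        .rename("cases")
        .reset_index()
        .rename(columns={"index_year": "year"})
        .sort_values(["year", "sex", "age_band"])
        .reset_index(drop=True)
    )
    return assignments, counts
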