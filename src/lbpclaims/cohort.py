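"""Cohort selection: restrict validated claims to the study population.

Keeps claims whose ICD-9 stem is a low-back stem, whose service date lies
in the extraction window, and whose patient reaches the minimum age during
the study (mid-year convention: age in year Y is Y − birth_year).  Patients
who turn 18 mid-study are kept — they can index from the first year they
are of age; the per-year age gate is applied when case-years are assigned.
"""

from __future__ import annotations

import pandas as pd

from .config import StudyConfig

__all__ = ["filter_cohort"]


def filter_cohort(claims: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Return the LBP study-cohort subset of ``claims``.

    Idempotent; never adds rows; output deterministically ordered by
    (patient_id, service_date, icd9).
    """
    stem = claims["icd9"].astype(str).str[:3]
    keep = stem.isin(config.lbp_stems)
    dates = pd.to_datetime(claims["service_date"])
    keep &= dates.between(
        pd.Timestamp(config.extraction_start), pd.Timestamp(config.extraction_end)
    )
    # age attained by the last study year; younger patients can never index
    last_year = config.study_years[1]
    keep &= (last_year - claims["birth_year"].astype(int)) >= config.min_age
    out = claims.loc[keep].copy()
    out["service_date"] = pd.to_datetime(out["service_date"])
    out = out.sort_values(
        ["patient_id", "service_date", "icd9"], kind="mergesort"
    ).reset_index(drop=True)
    return out
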