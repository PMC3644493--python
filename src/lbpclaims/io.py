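"""Reading and writing claims, denominators, and study configuration.

Claims travel through the pipeline as a pandas DataFrame with columns
``patient_id`` (opaque string token), ``sex`` ("male"/"female"),
``birth_year`` (int), ``service_date`` (datetime64[ns]) and ``icd9``
(3-digit stem plus optional fourth digit, e.g. "7242" or "724").  The CSV
dialect is fixed — comma-separated, UTF-8, ISO-8601 dates, mandatory
header — so written files are bit-stable.

Row validation never drops data silently: :func:`read_claims` returns a
:class:`ReadReport` counting and describing every rejected row, and a
strict flag turns any reject into a hard error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .config import StudyConfig, band_labels

__all__ = [
    "ClaimRecord",
    "ReadReport",
    "SchemaError",
    "ClaimValidationError",
    "CLAIMS_COLUMNS",
    "DENOM_COLUMNS",
    "read_claims",
    "write_claims",
    "records_to_frame",
    "frame_to_records",
    "read_denominators",
    "write_denominators",
    "read_config",
    "write_config",
]

CLAIMS_COLUMNS = ["patient_id", "sex", "birth_year", "service_date", "icd9"]
DENOM_COLUMNS = ["year", "sex", "age_band", "count"]

_SEXES = ("male", "female")


class SchemaError(ValueError):
    """The file header does not match the documented column schema."""


class ClaimValidationError(ValueError):
    """A row failed validation under strict reading."""


@dataclass(frozen=True)
class ClaimRecord:
    """One billed physician visit.

    ``icd9`` carries the code as billed; :attr:`stem` is the 3-digit
    grouping used by the recurrence rule, the full code is what the
    diagnosis classifier consumes.
    """

    patient_id: str
    sex: str
    birth_year: int
    service_date: "pd.Timestamp"
    icd9: str

    @property
    def stem(self) -> str:
        return self.icd9[:3]


@dataclass
class ReadReport:
    """Outcome of one :func:`read_claims` call."""

    n_read: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    reasons: dict[str, int] = dataclasses.field(default_factory=dict)

    def add(self, reason: str, count: int) -> None:
        if count:
            self.n_rejected += count
            self.reasons[reason] = self.reasons.get(reason, 0) + int(count)


def _validate_frame(
    df: pd.DataFrame, config: Optional[StudyConfig]
) -> tuple[pd.DataFrame, ReadReport]:
    report = ReadReport(n_read=len(df))
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["icd9"] = df["icd9"].astype(str).str.strip()
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()

    ok = pd.Series(True, index=df.index)

    bad = ~df["sex"].isin(_SEXES)
    report.add("invalid sex", int(bad.sum()))
    ok &= ~bad

    birth = pd.to_numeric(df["birth_year"], errors="coerce")
    bad = (birth.isna() | (birth % 1 != 0)) & ok
    report.add("unparseable birth_year", int(bad.sum()))
    ok &= ~bad
    df["birth_year"] = birth.fillna(-1).astype(int)

    dates = pd.to_datetime(df["service_date"], format="%Y-%m-%d", errors="coerce")
    bad = dates.isna() & ok
    report.add("unparseable service_date", int(bad.sum()))
    ok &= ~bad
    df["service_date"] = dates

    stem = df["icd9"].str[:3]
    stem_ok = (
        stem.str.len().eq(3)
        & stem.str.isdigit()
        & df["icd9"].str.len().isin([3, 4])
        & df["icd9"].str.isdigit()
    )
    # stems must parse as 001-999
    stem_ok &= pd.to_numeric(stem, errors="coerce").fillna(0).between(1, 999)
    bad = ~stem_ok & ok
    report.add("invalid icd9 code", int(bad.sum()))
    ok &= ~bad

    if config is not None:
        lo = pd.Timestamp(config.extraction_start)
        hi = pd.Timestamp(config.extraction_end)
        bad = (~df["service_date"].between(lo, hi)) & ok
        report.add("service_date outside extraction window", int(bad.sum()))
        ok &= ~bad

    out = df.loc[ok, CLAIMS_COLUMNS].reset_index(drop=True)
    report.n_valid = len(out)
    return out, report


def read_claims(
    path: Union[str, Path],
    config: Optional[StudyConfig] = None,
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a claims CSV.

    Parameters
    ----------
    path
        CSV with header ``patient_id,sex,birth_year,service_date,icd9``.
    config
        When given, rows dated outside the extraction window are rejected.
    strict
        Fail fast on the first invalid row instead of skip-with-count.

    Returns
    -------
    (claims, report)
        Validated claims frame and the tally of rejected rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"claims file {path} missing columns: {missing}")
    out, report = _validate_frame(df, config)
    if strict and report.n_rejected:
        detail = ", ".join(f"{k}: {v}" for k, v in report.reasons.items())
        raise ClaimValidationError(
            f"{report.n_rejected} invalid row(s) in {path} ({detail})"
        )
    return out, report


def write_claims(claims: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write claims in the canonical CSV dialect (ISO dates, fixed columns)."""
    out = claims.loc[:, CLAIMS_COLUMNS].copy()
    out["service_date"] = pd.to_datetime(out["service_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def records_to_frame(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    rows = [
        (r.patient_id, r.sex, r.birth_year, pd.Timestamp(r.service_date), r.icd9)
        for r in records
    ]
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def frame_to_records(claims: pd.DataFrame) -> list[ClaimRecord]:
    return [
        ClaimRecord(
            str(row.patient_id),
            row.sex,
            int(row.birth_year),
            pd.Timestamp(row.service_date),
            str(row.icd9),
        )
        for row in claims.itertuples(index=False)
    ]


def read_denominators(
    path: Union[str, Path], config: Optional[StudyConfig] = None
) -> pd.DataFrame:
    """Read population denominators (columns year,sex,age_band,count)."""
    df = pd.read_csv(path)
    missing = [c for c in DENOM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"denominator file {path} missing columns: {missing}")
    df = df.loc[:, DENOM_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    df["sex"] = df["sex"].astype(str).str.lower()
    df["age_band"] = df["age_band"].astype(str)
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        raise ValueError("denominator counts must be non-negative")
    if not df["sex"].isin(_SEXES).all():
        raise ValueError("denominator sex must be male/female")
    if config is not None:
        known = set(band_labels(config.bands))
        unknown = sorted(set(df["age_band"]) - known)
        if unknown:
            raise ValueError(f"unknown age bands in denominators: {unknown}")
    return df.sort_values(DENOM_COLUMNS[:3]).reset_index(drop=True)


def write_denominators(denoms: pd.DataFrame, path: Union[str, Path]) -> None:
    denoms.loc[:, DENOM_COLUMNS].to_csv(path, index=False)


def read_config(path: Union[str, Path]) -> StudyConfig:
    """Load a StudyConfig from a flat YAML key/value document."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return StudyConfig.from_dict(data)


def write_config(config: StudyConfig, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
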