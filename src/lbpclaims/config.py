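"""Study configuration and age-band definitions.

The study window, diagnosis-code set, and recurrence rule are all
configurable; the defaults reproduce the Québec claims-surveillance design:
adults (18+), ICD-9 low-back stems {721, 722, 724, 739}, at least three
identical-stem diagnoses within a 365-day period, study years 2000-2007
inside a 1999-2008 extraction window, 99% confidence for all intervals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "AgeBand",
    "REPORTING_BANDS",
    "FIVE_YEAR_BANDS",
    "band_of",
    "band_labels",
    "StudyConfig",
    "DEFAULT_LBP_STEMS",
]

DEFAULT_LBP_STEMS = frozenset({"721", "722", "724", "739"})


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lo, hi); ``hi=None`` means open-ended."""

    label: str
    lo: int
    hi: Optional[int]

    def contains(self, age: int) -> bool:
        return age >= self.lo and (self.hi is None or age < self.hi)


#: Reporting bands used for the stratified prevalence/risk tables.
REPORTING_BANDS: tuple[AgeBand, ...] = (
    AgeBand("18-34", 18, 35),
    AgeBand("35-49", 35, 50),
    AgeBand("50-64", 50, 65),
    AgeBand("65-80", 65, 80),
    AgeBand("80+", 80, None),
)

#: Finer 5-year bands for age-profile curves.
FIVE_YEAR_BANDS: tuple[AgeBand, ...] = (
    AgeBand("18-19", 18, 20),
    *(
        AgeBand(f"{lo}-{lo + 4}", lo, lo + 5)
        for lo in range(20, 85, 5)
    ),
    AgeBand("85+", 85, None),
)


def band_of(age: int, bands: Sequence[AgeBand] = REPORTING_BANDS) -> Optional[str]:
    """Label of the band containing ``age``, or None if below every band."""
    for b in bands:
        if b.contains(age):
            return b.label
    return None


def band_labels(bands: Sequence[AgeBand] = REPORTING_BANDS) -> list[str]:
    return [b.label for b in bands]


def _check_partition(bands: Sequence[AgeBand]) -> None:
    ordered = sorted(bands, key=lambda b: b.lo)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.hi is None or prev.hi != nxt.lo:
            raise ValueError(
                f"age bands must partition [{ordered[0].lo}, inf) without "
                f"gaps or overlap; {prev.label!r} and {nxt.label!r} do not abut"
            )
    if ordered[-1].hi is not None:
        raise ValueError("last age band must be open-ended")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of the recurrence phenotype and the surveillance layer.

    Parameters
    ----------
    lbp_stems
        3-digit ICD-9 stems that count as low back pain.
    window_days
        Length of the recurrence window in days (a "365-day period").
    min_claims
        Minimum number of identical diagnoses inside one window.
    study_years
        Inclusive (first, last) index years that receive case assignments.
    extraction_start, extraction_end
        Claim extraction window; wider than the study years so windows can
        straddle the first/last study year.
    min_age
        Minimum age (mid-year convention: year − birth_year).
    confidence
        Confidence level shared by every interval (Wilson and risk-ratio).
    span_inclusive
        If True, a window span of exactly ``window_days`` qualifies
        (sensitivity analysis); default requires span < window_days.
    distinct_dates
        If True (default), same-day repeat billings of one stem count as a
        single diagnosis occurrence.
    stem_identity
        If True (default), "identical diagnoses" are compared at the 3-digit
        stem; if False, full 4-digit identity is required.
    seed
        Seed for any randomised component downstream.
    """

    lbp_stems: frozenset[str] = DEFAULT_LBP_STEMS
    window_days: int = 365
    min_claims: int = 3
    study_years: tuple[int, int] = (2000, 2007)
    extraction_start: dt.date = dt.date(1999, 1, 1)
    extraction_end: dt.date = dt.date(2008, 12, 31)
    min_age: int = 18
    confidence: float = 0.99
    span_inclusive: bool = False
    distinct_dates: bool = True
    stem_identity: bool = True
    bands: tuple[AgeBand, ...] = REPORTING_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_claims < 1:
            raise ValueError("min_claims must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie strictly between 0 and 1")
        first, last = self.study_years
        if first > last:
            raise ValueError("study_years must be an inclusive (first, last) pair")
        if first < self.extraction_start.year or last > self.extraction_end.year:
            raise ValueError("study_years must lie within the extraction window")
        if self.extraction_start > self.extraction_end:
            raise ValueError("extraction window is empty")
        for stem in self.lbp_stems:
            if not (len(stem) == 3 and stem.isdigit() and 1 <= int(stem) <= 999):
                raise ValueError(f"invalid 3-digit ICD-9 stem: {stem!r}")
        _check_partition(self.bands)
        object.__setattr__(self, "lbp_stems", frozenset(self.lbp_stems))
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def years(self) -> range:
        """Iterable of index years, first through last inclusive."""
        return range(self.study_years[0], self.study_years[1] + 1)

    def replace(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)

    # -- flat key/value (de)serialisation ------------------------------

    def to_dict(self) -> dict:
        return {
            "lbp_stems": sorted(self.lbp_stems),
            "window_days": self.window_days,
            "min_claims": self.min_claims,
            "study_years": list(self.study_years),
            "extraction_start": self.extraction_start.isoformat(),
            "extraction_end": self.extraction_end.isoformat(),
            "min_age": self.min_age,
            "confidence": self.confidence,
            "span_inclusive": self.span_inclusive,
            "distinct_dates": self.distinct_dates,
            "stem_identity": self.stem_identity,
            "bands": [[b.label, b.lo, b.hi] for b in self.bands],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = dict(d)
        if "lbp_stems" in kwargs:
            kwargs["lbp_stems"] = frozenset(str(s) for s in kwargs["lbp_stems"])
        if "study_years" in kwargs:
            kwargs["study_years"] = tuple(kwargs["study_years"])
        for key in ("extraction_start", "extraction_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        if "bands" in kwargs:
            kwargs["bands"] = tuple(
                AgeBand(label, lo, hi) for label, lo, hi in kwargs["bands"]
            )
        return cls(**kwargs)
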