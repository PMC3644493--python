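"""Synthetic physician-claims generator with known ground truth.

The real single-payer billing registry behind the surveillance estimates is
not publicly accessible, so every downstream stage is exercised on
synthetic extracts in the identical format.  Each (year, sex, age-band)
stratum is simulated as a cross-section of ``population`` adults:

* a Binomial(population, π) number become **cases** — their claim history
  for that index year contains ``min_claims`` + Poisson extra claims with
  one identical ICD-9 stem, on distinct dates inside an episode window
  whose span stays safely below the recurrence window and inside the
  calendar year, so the truth table is exact by construction;
* a fraction of the rest become **background consulters** whose LBP claims
  are spaced more than the recurrence window apart (and may fall in the
  buffer years at the edges of the extraction window), so they can never
  qualify — prevalence recovered from the pipeline then estimates π alone;
* an optional **hard-negative** fraction receives three tightly clustered
  claims with three different stems, exercising the identical-stem rule.

Diagnosis codes are drawn from a mixture over the 4-digit Cherkin codes;
the default mixture follows the published 2000 category frequencies,
spread uniformly over the codes within each category.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .categories import CHERKIN_CATEGORIES
from .config import AgeBand, StudyConfig

__all__ = [
    "StratumSpec",
    "SimulationScenario",
    "ScenarioError",
    "default_code_mixture",
    "generate",
    "scenario_from_prevalence_table",
]


class ScenarioError(ValueError):
    """The scenario cannot produce claims satisfying the phenotype."""


@dataclass(frozen=True)
class StratumSpec:
    """One simulated (year, sex, age-band) cross-section."""

    year: int
    sex: str
    age_band: str
    population: int
    pi: float  # true recurrent-LBP proportion, in [0, 1]


def default_code_mixture() -> Dict[str, float]:
    """Mixture over 4-digit codes matching the published 2000 category mix."""
    total = sum(reference.CHERKIN_COUNTS_2000.values())
    mix: Dict[str, float] = {}
    for cat, codes in CHERKIN_CATEGORIES.items():
        share = reference.CHERKIN_COUNTS_2000[cat] / total
        for code in sorted(codes):
            mix[code] = share / len(codes)
    return mix


@dataclass
class SimulationScenario:
    """Full description of one synthetic claims universe.

    Visit-process defaults: cases get ``min_claims`` + Poisson(1.5) claims
    in an episode of 30-300 days; 6% of non-cases consult for LBP at all
    (roughly the annual any-LBP consultation rate in adult populations),
    with 1 + Poisson(0.6) claims spaced 366-550 days apart.
    """

    strata: list[StratumSpec]
    case_extra_claims_mean: float = 1.5
    episode_span_min: int = 30
    episode_span_max: int = 300
    background_rate: float = 0.06
    background_extra_claims_mean: float = 0.6
    background_gap_min: int = 366
    background_gap_max: int = 550
    hard_negative_rate: float = 0.0
    code_mixture: Dict[str, float] = field(default_factory=default_code_mixture)
    seed: int = 0

    def validate(self, config: StudyConfig) -> None:
        if not self.strata:
            raise ScenarioError("scenario has no strata")
        for st in self.strata:
            if not 0.0 <= st.pi <= 1.0:
                raise ScenarioError(f"pi out of [0,1] for stratum {st}")
            if st.population < 0:
                raise ScenarioError(f"negative population for stratum {st}")
            if not (config.extraction_start.year <= st.year <= config.extraction_end.year):
                raise ScenarioError(f"stratum year {st.year} outside extraction window")
        if self.episode_span_max >= config.window_days:
            raise ScenarioError(
                "episode span distribution exceeds the recurrence window: "
                f"max span {self.episode_span_max} >= {config.window_days} days"
            )
        if not (config.min_claims - 1 <= self.episode_span_min <= self.episode_span_max):
            raise ScenarioError("episode_span_min must lie in [min_claims-1, span_max]")
        if self.background_gap_min <= config.window_days:
            raise ScenarioError(
                "background inter-claim gaps must exceed the recurrence window "
                "for the separation guarantee"
            )
        total = sum(self.code_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ScenarioError(f"code mixture sums to {total}, not 1")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ScenarioError("background_rate must lie in [0,1]")
        if not 0.0 <= self.hard_negative_rate <= 1.0:
            raise ScenarioError("hard_negative_rate must lie in [0,1]")
        stems = {c[:3] for c in self.code_mixture}
        if not stems <= config.lbp_stems:
            raise ScenarioError("code mixture contains non-LBP stems")


def _band_age_range(label: str, config: StudyConfig) -> tuple[int, int]:
    for b in config.bands:
        if b.label == label:
            return b.lo, (b.hi if b.hi is not None else b.lo + 16)
    raise ScenarioError(f"age band {label!r} not in the configured band set")


def _year_bounds(year: int) -> tuple[int, int]:
    start = np.datetime64(f"{year}-01-01", "D").astype(np.int64)
    end = np.datetime64(f"{year + 1}-01-01", "D").astype(np.int64)
    return int(start), int(end)


class _CodeSampler:
    """Vectorised draws from the 4-digit code mixture."""

    def __init__(self, mixture: Mapping[str, float]):
        self.codes = np.array(sorted(mixture))
        probs = np.array([mixture[c] for c in self.codes], dtype=float)
        probs /= probs.sum()
        self.cum = np.cumsum(probs)
        self.stems = np.array(sorted({c[:3] for c in mixture}))
        stem_of = np.array([c[:3] for c in self.codes])
        self.stem_probs = np.array(
            [probs[stem_of == s].sum() for s in self.stems]
        )
        self._by_stem = {}
        for s in self.stems:
            m = stem_of == s
            p = probs[m] / probs[m].sum()
            self._by_stem[s] = (self.codes[m], np.cumsum(p))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.codes[np.searchsorted(self.cum, rng.random(size))]

    def draw_stems(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.stem_probs / self.stem_probs.sum()
        return rng.choice(self.stems, size=size, p=p)

    def draw_within_stem(
        self, rng: np.random.Generator, stems: np.ndarray
    ) -> np.ndarray:
        out = np.empty(len(stems), dtype=self.codes.dtype)
        u = rng.random(len(stems))
        for s in self.stems:
            m = stems == s
            if m.any():
                codes, cum = self._by_stem[s]
                out[m] = codes[np.searchsorted(cum, u[m])]
        return out


def generate(
    scenario: SimulationScenario,
    config: Optional[StudyConfig] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one claims extract with matching denominators and truth.

    Returns
    -------
    (claims, denominators, truth)
        ``claims`` in the canonical claims-frame layout (integer patient
        tokens); ``denominators`` with columns year,sex,age_band,count
        equal to the simulated population sizes; ``truth`` with one row
        per true case patient-year (patient_id, year, sex, age_band).

    Deterministic given the seed (``seed`` argument overrides
    ``scenario.seed``).
    """
    config = config or StudyConfig()
    scenario.validate(config)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sampler = _CodeSampler(scenario.code_mixture)

    ext_start = np.datetime64(config.extraction_start, "D").astype(np.int64)
    ext_end = np.datetime64(config.extraction_end, "D").astype(np.int64)

    pid_counter = 0
    claim_parts: list[pd.DataFrame] = []
    truth_parts: list[pd.DataFrame] = []
    denom_rows: list[tuple] = []

    for st in scenario.strata:
        denom_rows.append((st.year, st.sex, st.age_band, st.population))
        if st.population == 0:
            continue
        age_lo, age_hi = _band_age_range(st.age_band, config)
        y_start, y_end = _year_bounds(st.year)
        year_len = y_end - y_start

        k = int(rng.binomial(st.population, st.pi)) if st.pi > 0 else 0
        rest = st.population - k
        nb = int(rng.binomial(rest, scenario.background_rate))
        nh = int(rng.binomial(rest - nb, scenario.hard_negative_rate))

        # --- cases -------------------------------------------------
        if k:
            m = config.min_claims + rng.poisson(scenario.case_extra_claims_mean, k)
            m = np.minimum(m, scenario.episode_span_min + 1)
            span = rng.integers(
                scenario.episode_span_min, scenario.episode_span_max + 1, k
            )
            span = np.maximum(span, m - 1)
            start = y_start + rng.integers(0, year_len - span)
            total = int(m.sum())
            case_idx = np.repeat(np.arange(k), m)
            bound = (span - m + 2)[case_idx]
            base = np.floor(rng.random(total) * bound).astype(np.int64)
            order = np.lexsort((base, case_idx))
            offsets_starts = np.concatenate(([0], np.cumsum(m)[:-1]))
            j = np.arange(total) - offsets_starts[case_idx]
            days = start[case_idx] + base[order] + j

            stems = sampler.draw_stems(rng, k)
            codes = sampler.draw_within_stem(rng, stems[case_idx])
            ages = rng.integers(age_lo, age_hi, k)
            pids = pid_counter + np.arange(k)
            pid_counter += k

            claim_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[case_idx],
                        "sex": st.sex,
                        "birth_year": (st.year - ages)[case_idx],
                        "service_date": days.astype("datetime64[D]"),
                        "icd9": codes,
                    }
                )
            )
            truth_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pids,
                        "year": st.year,
                        "sex": st.sex,
                        "age_band": st.age_band,
                    }
                )
            )

        # --- background consulters (never qualify) ------------------
        if nb:
            c = 1 + rng.poisson(scenario.background_extra_claims_mean, nb)
            total = int(c.sum())
            pat_idx = np.repeat(np.arange(nb), c)
            first = rng.integers(ext_start, ext_end + 1, nb)
            gaps = rng.integers(
                scenario.background_gap_min, scenario.background_gap_max + 1, total
            )
            starts_cum = np.concatenate(([0], np.cumsum(c)[:-1]))
            jj = np.arange(total) - starts_cum[pat_idx]
            # accumulate gaps within patient (first claim contributes 0)
            gap_cum = np.cumsum(np.where(jj > 0, gaps, 0))
            resets = gap_cum[starts_cum[pat_idx]]
            days = first[pat_idx] + gap_cum - resets
            keep = days <= ext_end
            pat_idx, days = pat_idx[keep], days[keep]

            codes = sampler.draw(rng, len(days))
            ages = rng.integers(age_lo, age_hi, nb)
            pids = pid_counter + np.arange(nb)
            pid_counter += nb
            claim_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[pat_idx],
                        "sex": st.sex,
                        "birth_year": (st.year - ages)[pat_idx],
                        "service_date": days.astype("datetime64[D]"),
                        "icd9": codes,
                    }
                )
            )

        # --- hard negatives: 3 tight claims, 3 different stems ------
        if nh:
            hn_stems = sorted(config.lbp_stems)[:3]
            start = rng.integers(y_start, y_end - 30, nh)
            g1 = rng.integers(1, 15, nh)
            g2 = rng.integers(1, 15, nh)
            days = np.concatenate([start, start + g1, start + g1 + g2])
            stems = np.repeat(np.array(hn_stems), nh)
            codes = sampler.draw_within_stem(rng, stems)
            ages = rng.integers(age_lo, age_hi, nh)
            pids = pid_counter + np.arange(nh)
            pid_counter += nh
            claim_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": np.tile(pids, 3),
                        "sex": st.sex,
                        "birth_year": np.tile(st.year - ages, 3),
                        "service_date": days.astype("datetime64[D]"),
                        "icd9": codes,
                    }
                )
            )

    if claim_parts:
        claims = pd.concat(claim_parts, ignore_index=True)
        claims["service_date"] = claims["service_date"].astype("datetime64[ns]")
        claims = claims.sort_values(
            ["patient_id", "service_date", "icd9"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        claims = pd.DataFrame(
            columns=["patient_id", "sex", "birth_year", "service_date", "icd9"]
        )
    denominators = pd.DataFrame(
        denom_rows, columns=["year", "sex", "age_band", "count"]
    )
    if truth_parts:
        truth = pd.concat(truth_parts, ignore_index=True).sort_values(
            ["patient_id", "year"]
        ).reset_index(drop=True)
    else:
        truth = pd.DataFrame(columns=["patient_id", "year", "sex", "age_band"])
    return claims, denominators, truth


def scenario_from_prevalence_table(
    prevalence_pct: Optional[Mapping[tuple[str, str], tuple[float, float]]] = None,
    population: int = 100_000,
    years: Optional[Iterable[int]] = None,
    endpoint_years: tuple[int, int] = reference.ENDPOINT_YEARS,
    **overrides,
) -> SimulationScenario:
    """Scenario whose true π values follow the published stratified table.

    Each (sex, age band) stratum gets the printed endpoint-year prevalences
    (percent) as its true proportions, linearly interpolated for the years
    in between: ``π_y = a + (y − y0)·(b − a)/(y1 − y0)``.

    Parameters
    ----------
    prevalence_pct
        (sex, band) -> (percent at first endpoint, percent at last);
        defaults to the published values.
    population
        Simulated population per stratum-year.
    years
        Years to simulate; defaults to the two endpoint years.
    overrides
        Passed through to :class:`SimulationScenario`.
    """
    table = dict(prevalence_pct or reference.PREVALENCE_PCT)
    y0, y1 = endpoint_years
    if years is None:
        years = endpoint_years
    strata = []
    for (sex, band), (a_pct, b_pct) in table.items():
        for year in years:
            frac = (year - y0) / (y1 - y0)
            if not 0.0 <= frac <= 1.0:
                raise ScenarioError(f"year {year} outside endpoint range {endpoint_years}")
            pi = (a_pct + frac * (b_pct - a_pct)) / 100.0
            strata.append(StratumSpec(year, sex, band, population, pi))
    strata.sort(key=lambda s: (s.year, s.sex, s.age_band))
    return SimulationScenario(strata=strata, **overrides)
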