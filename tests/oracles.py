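"""Independent reference implementations used only by the test suite.

Each oracle deliberately takes a different route from the library code it
checks: the case-year oracle enumerates every claim combination instead of
sliding a window, and the Wilson oracle inverts the score test numerically
instead of using the closed form.
"""

from __future__ import annotations

import math
from itertools import combinations

from scipy.optimize import brentq
from scipy.stats import norm

from lbpclaims import StudyConfig


def brute_force_case_years(claims, config: StudyConfig) -> set[int]:
    """Case years by exhaustive enumeration of all min_claims-subsets.

    ``claims``: iterable of (date, icd9) pairs for one patient.
    """
    key = (lambda c: c[:3]) if config.stem_identity else (lambda c: c)
    items = [(key(str(c)), d) for d, c in claims]
    if config.distinct_dates:
        items = sorted(set(items))
    limit = config.window_days if config.span_inclusive else config.window_days - 1
    first_year, last_year = config.study_years

    by_key: dict[str, list] = {}
    for s, d in items:
        by_key.setdefault(s, []).append(d)

    years: set[int] = set()
    for days in by_key.values():
        for combo in combinations(sorted(days), config.min_claims):
            if (combo[-1] - combo[0]).days <= limit:
                for d in combo:
                    if first_year <= d.year <= last_year:
                        years.add(d.year)
    return years


def wilson_by_bisection(k: int, n: int, confidence: float) -> tuple[float, float]:
    """Wilson bounds found by inverting the score test with root-finding.

    The bounds are the p solving |p̂ − p| = z·sqrt(p(1−p)/n) on either side
    of p̂; solved with Brent's method to ~1e-14.
    """
    z = norm.ppf(0.5 + confidence / 2.0)
    phat = k / n

    def below(p):  # zero at the lower bound
        return (phat - p) - z * math.sqrt(p * (1.0 - p) / n)

    def above(p):  # zero at the upper bound
        return (p - phat) - z * math.sqrt(p * (1.0 - p) / n)

    # brackets avoid the spurious roots of the score equation at p in {0, 1}
    lo_hi = 1.0 - 1e-12 if k == n else phat
    hi_lo = 1e-12 if k == 0 else phat
    lower = 0.0 if k == 0 else brentq(below, 1e-16, lo_hi, xtol=1e-15, rtol=1e-15)
    upper = 1.0 if k == n else brentq(above, hi_lo, 1.0, xtol=1e-15, rtol=1e-15)
    return lower, upper
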