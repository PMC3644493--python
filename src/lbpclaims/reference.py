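"""Published Québec surveillance values for claims-based recurrent LBP.

These are the printed 2000/2007 estimates from the Québec physician-claims
surveillance of recurrent low back pain: stratified prevalence (percent)
with endpoint comparison columns, men-vs-women relative risks, and the
Cherkin-category claim counts.  They serve two purposes here:

* inputs to :func:`lbpclaims.simulate.scenario_from_prevalence_table`, which builds a
  synthetic population whose true stratum prevalences equal these values;
* anchors for internal-consistency checks (a relative risk recomputed from
  the two printed prevalences of a stratum must match the printed relative
  risk, and likewise for percent variations and category shares).

The underlying person-level registry is not publicly available, so these
printed aggregates are the only real-data quantities the package consumes.
"""

from __future__ import annotations

__all__ = [
    "PREVALENCE_PCT",
    "PREVALENCE_CI",
    "PERCENT_VARIATION",
    "SLOPE",
    "RELATIVE_RISK",
    "RELATIVE_RISK_CI",
    "CHERKIN_COUNTS_2000",
    "CHERKIN_COUNTS_2007",
    "CHERKIN_SHARES_2000",
    "CHERKIN_SHARES_2007",
    "CHERKIN_PCT_CHANGE",
    "SEXES",
    "BANDS",
    "ENDPOINT_YEARS",
]

SEXES = ("male", "female")
BANDS = ("18-34", "35-49", "50-64", "65-80", "80+")
ENDPOINT_YEARS = (2000, 2007)

#: (sex, age band) -> annual prevalence percent in (2000, 2007).
PREVALENCE_PCT: dict[tuple[str, str], tuple[float, float]] = {
    ("male", "18-34"): (1.13, 0.70),
    ("female", "18-34"): (0.89, 0.64),
    ("male", "35-49"): (2.05, 1.63),
    ("female", "35-49"): (1.65, 1.45),
    ("male", "50-64"): (1.93, 1.68),
    ("female", "50-64"): (1.78, 1.55),
    ("male", "65-80"): (1.36, 1.33),
    ("female", "65-80"): (1.72, 1.79),
    ("male", "80+"): (1.29, 1.35),
    ("female", "80+"): (1.58, 1.83),
}

#: (sex, age band, year) -> printed 99% CI bounds, percent.
PREVALENCE_CI: dict[tuple[str, str, int], tuple[float, float]] = {
    ("male", "18-34", 2000): (1.10, 1.16),
    ("male", "18-34", 2007): (0.68, 0.73),
    ("female", "18-34", 2000): (0.87, 0.92),
    ("female", "18-34", 2007): (0.62, 0.66),
    ("male", "35-49", 2000): (2.01, 2.09),
    ("male", "35-49", 2007): (1.59, 1.66),
    ("female", "35-49", 2000): (1.62, 1.69),
    ("female", "35-49", 2007): (1.41, 1.48),
    ("male", "50-64", 2000): (1.89, 1.98),
    ("male", "50-64", 2007): (1.64, 1.72),
    ("female", "50-64", 2000): (1.73, 1.82),
    ("female", "50-64", 2007): (1.52, 1.59),
    ("male", "65-80", 2000): (1.31, 1.41),
    ("male", "65-80", 2007): (1.29, 1.38),
    ("female", "65-80", 2000): (1.67, 1.78),
    ("female", "65-80", 2007): (1.74, 1.84),
    ("male", "80+", 2000): (1.18, 1.41),
    ("male", "80+", 2007): (1.26, 1.45),
    ("female", "80+", 2000): (1.50, 1.67),
    ("female", "80+", 2007): (1.75, 1.91),
}

#: (sex, age band) -> printed endpoint percent variation (integer percent).
PERCENT_VARIATION: dict[tuple[str, str], int] = {
    ("male", "18-34"): -38,
    ("female", "18-34"): -28,
    ("male", "35-49"): -21,
    ("female", "35-49"): -12,
    ("male", "50-64"): -13,
    ("female", "50-64"): -13,
    ("male", "65-80"): -2,
    ("female", "65-80"): 4,
    ("male", "80+"): 5,
    ("female", "80+"): 16,
}

#: (sex, age band) -> printed trend slope, prevalence percent per year.
SLOPE: dict[tuple[str, str], float] = {
    ("male", "18-34"): -0.061,
    ("female", "18-34"): -0.033,
    ("male", "35-49"): -0.062,
    ("female", "35-49"): -0.027,
    ("male", "50-64"): -0.032,
    ("female", "50-64"): -0.028,
    ("male", "65-80"): -0.001,
    ("female", "65-80"): 0.016,
    ("male", "80+"): 0.004,
    ("female", "80+"): 0.005,
}

#: (age band, year) -> printed male:female relative risk.
RELATIVE_RISK: dict[tuple[str, int], float] = {
    ("18-34", 2000): 1.26,
    ("18-34", 2007): 1.10,
    ("35-49", 2000): 1.24,
    ("35-49", 2007): 1.12,
    ("50-64", 2000): 1.09,
    ("50-64", 2007): 1.08,
    ("65-80", 2000): 0.79,
    ("65-80", 2007): 0.75,
    ("80+", 2000): 0.81,
    ("80+", 2007): 0.74,
}

#: (age band, year) -> printed 99% CI for the relative risk.
RELATIVE_RISK_CI: dict[tuple[str, int], tuple[float, float]] = {
    ("18-34", 2000): (1.22, 1.32),
    ("18-34", 2007): (1.05, 1.16),
    ("35-49", 2000): (1.20, 1.27),
    ("35-49", 2007): (1.09, 1.16),
    ("50-64", 2000): (1.05, 1.13),
    ("50-64", 2007): (1.05, 1.12),
    ("65-80", 2000): (0.75, 0.83),
    ("65-80", 2007): (0.72, 0.79),
    ("80+", 2000): (0.73, 0.90),
    ("80+", 2007): (0.69, 0.81),
}

#: Relative-risk cells whose printed value equals the ratio of the two
#: printed prevalences at 2-decimal rounding.  The remaining cells differ
#: in the second decimal because the published prevalences are themselves
#: rounded to two decimals before the ratio is taken.
RECONCILABLE_RR_CELLS: tuple[tuple[str, int], ...] = (
    ("35-49", 2000),
    ("35-49", 2007),
    ("50-64", 2007),
    ("65-80", 2000),
    ("80+", 2007),
)

#: Cherkin-category claim counts in the two comparison years.
CHERKIN_COUNTS_2000: dict[str, int] = {
    "Herniated disc": 5270,
    "Probably degenerative changes": 70162,
    "Spinal stenosis": 7250,
    "Possible instability": 655,
    "Non-specific back aches": 254385,
    "Sequelae of previous back surgery": 8,
    "Miscellaneous": 42422,
}

CHERKIN_COUNTS_2007: dict[str, int] = {
    "Herniated disc": 5825,
    "Probably degenerative changes": 57764,
    "Spinal stenosis": 12765,
    "Possible instability": 415,
    "Non-specific back aches": 218228,
    "Sequelae of previous back surgery": 212,
    "Miscellaneous": 39224,
}

#: Printed shares of all classified claims, percent.
CHERKIN_SHARES_2000: dict[str, float] = {
    "Herniated disc": 1.4,
    "Probably degenerative changes": 18.5,
    "Spinal stenosis": 1.9,
    "Possible instability": 0.2,
    "Non-specific back aches": 66.9,
    "Sequelae of previous back surgery": 0.0,
    "Miscellaneous": 11.2,
}

CHERKIN_SHARES_2007: dict[str, float] = {
    "Herniated disc": 2.0,
    "Probably degenerative changes": 17.2,
    "Spinal stenosis": 3.8,
    "Possible instability": 0.1,
    "Non-specific back aches": 65.1,
    "Sequelae of previous back surgery": 0.1,
    "Miscellaneous": 11.7,
}

#: Printed within-category percent change 2000 -> 2007 (integer percent).
CHERKIN_PCT_CHANGE: dict[str, int] = {
    "Herniated disc": 11,
    "Probably degenerative changes": -18,
    "Spinal stenosis": 43,
    "Possible instability": -37,
    "Non-specific back aches": -14,
    "Sequelae of previous back surgery": 2650,
    "Miscellaneous": 8,
}

#: Rows whose printed within-category change is reproduced by
#: 100*(n_2007-n_2000)/n_2000 at integer rounding.  The other rows do not
#: follow that convention (the published stenosis/surgery-sequelae/
#: miscellaneous figures are irreconcilable with their own count columns).
RECONCILABLE_CHANGE_ROWS: tuple[str, ...] = (
    "Herniated disc",
    "Probably degenerative changes",
    "Possible instability",
    "Non-specific back aches",
)

__all__ += ["RECONCILABLE_RR_CELLS", "RECONCILABLE_CHANGE_ROWS"]
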