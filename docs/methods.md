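# Methods

## The recurrence phenotype

The operational case definition is purely temporal: a patient is a
claims-based recurrent LBP case for index year *Y* if some set of at least
`min_claims` (default 3) diagnoses with one identical ICD-9 stem
(default stems 721, 722, 724, 739) falls within a `window_days`-day
period (default 365) with at least one member dated in *Y*. Three
interpretive choices were genuinely open and are resolved as follows, each
behind a configuration flag:

* **Window arithmetic.** A "365-day period" includes both endpoints, so
  the default requires `last − first ≤ 364` days (`span_inclusive=True`
  relaxes to ≤ 365 for sensitivity analysis).
* **Same-day repeat billing.** Multiple same-stem claims on one date
  collapse to a single diagnosis occurrence, equating diagnoses with
  consultations (`distinct_dates=False` counts raw claims instead).
* **Code identity.** "Identical" diagnoses are compared at the 3-digit
  stem — 7242 and 7245 match, 721x and 722x do not
  (`stem_identity=False` requires full 4-digit identity). Classification
  into Cherkin categories always uses the 4-digit code.

A year is attributed only when a member of a *qualifying* window falls in
it, not merely any LBP claim — the conservative reading of "one diagnosis
in the year under study".

**Algorithm.** Per (patient, stem), sort the distinct service dates and
slide a window of `min_claims` consecutive dates; a window qualifies when
its span fits, and every study year containing one of its dates is marked.
Correctness: any qualifying date set contains consecutive sorted dates
whose span is no larger, and within a qualifying window every member date
belongs to a consecutive sub-window of the same span, so the consecutive
scan marks exactly the years the exhaustive subset enumeration would.
The test suite checks this equivalence against a brute-force
all-combinations oracle on randomized patients (10⁴ patients in the bulk
run plus derandomised property tests), along with monotonicity under
added claims, permutation invariance, and duplication invariance.
The population-scale implementation is a vectorised (numpy) version of the
same scan; it is checked against the scalar reference on every oracle
instance.

**Age.** Age is mid-year age, `index_year − birth_year` — the standard
surveillance convention in the absence of exact birth dates. Case-years
are assigned only when that age reaches `min_age` (default 18); the cohort
filter keeps any patient who reaches `min_age` by the last study year, so
patients aging into the cohort mid-study contribute from their first
eligible year. Each case-year is banded independently, so a patient can
move age bands between case-years.

## Surveillance statistics

* **Prevalence**: 100·k/n per (year, sex, age-band) stratum; the
  denominators are external population counts, never derived from the
  claims. Strata with zero denominator are emitted as explicit missing
  rows. All-adult annual rates pool cases and denominators across bands
  before dividing (never an average of band rates).
* **Wilson score intervals** (via `statsmodels.stats.proportion`) at a
  confidence level shared across the package (default 99%). The closed
  form is verified in tests against an independent bisection inversion of
  the score test to 10⁻¹⁰, and its empirical 99% coverage at p = 0.015,
  n = 10⁵ is required to lie in [98%, 100%] over 2 000 draws. Bounds at
  k = 0 and k = n are snapped to the exact 0 and 1 the inversion yields.
* **Relative risk** male:female per band and year, with the Katz
  log-normal interval. The interval method for ratios is not dictated by
  the Wilson choice for proportions; Katz is the standard epidemiological
  default and is cross-checked against the log-method interval of
  `statsmodels` `Table2x2`. Zero event counts raise rather than produce
  degenerate intervals.
* **Trends**: OLS slope (scipy `linregress`) of the annual prevalence
  series on calendar year, and endpoint percent variation
  100·(last − first)/first. Report rounding follows the field's printed
  precision: prevalence and RR to 2 decimals, slopes to 3, percent
  variation to integers (half away from zero).

## The synthetic generator

Real single-payer billing registries are not redistributable, so the
generator produces structurally faithful extracts with exact ground
truth. Each (year, sex, band) stratum is an independent cross-section of
`population` adults:

* **Cases** (Binomial(`population`, π) of them): `min_claims` +
  Poisson(1.5) claims with a single stem drawn from the code-mixture's
  stem marginal, on distinct dates uniform (via order statistics with a
  spacing guarantee) inside an episode of 30-300 days placed uniformly
  within the index calendar year. Episode spans stay below the 365-day
  window, so every case qualifies by construction; episodes are confined
  to the index year so the truth table is exact — a case for year *Y* is
  never accidentally a case for *Y* ± 1.
* **Background consulters** (6% of non-cases — roughly the annual
  any-LBP physician-consultation rate in adult populations, an order of
  magnitude above the recurrent phenotype): 1 + Poisson(0.6) claims with
  consecutive gaps of 366-550 days, anywhere in the extraction window
  including the buffer years. Any three of their dates span > 730 days,
  so they can never qualify — the separation property that makes
  truth-vs-pipeline comparisons exact.
* **Hard negatives** (optional fraction): three claims within a month
  carrying three *different* stems, exercising the identical-stem rule.

Diagnosis codes follow a mixture over the 25 four-digit Cherkin codes
proportional to the published 2000 category frequencies, uniform within
category. Birth years are uniform within the band (the open 80+ band uses
ages 80-95). Output is deterministic given the seed; identical scenario +
seed gives byte-identical CSV files.

`scenario_from_prevalence_table` builds the default study scenario: true stratum
prevalences equal to the published Québec 2000/2007 stratified estimates,
linearly interpolated for intermediate years.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: longitudinal patient identity across years
(each stratum-year is a fresh cross-section, so multi-year case careers
and band transitions of one person are not simulated), disease course
(severity, chronicity transitions, care-seeking seasonality), non-LBP
comorbidity claims, coding error and upcoding, and regional or provider
clustering. The parameter-recovery results validate the pipeline's
arithmetic and the phenotype's implementation, not the clinical validity
of the case definition.

## Validation problem sizes

The recovery study simulates the two endpoint reporting years × 10
sex/band strata at 100 000 persons per stratum, 200 reseeded replicates
(100 in the acceptance script), and requires the pipeline's 99% Wilson
interval to cover the true π in ≥ 98% of the 4 000 stratum draws.
The end-to-end trend-pattern check runs at 200 000 per stratum and
asserts the recovered 2000→2007 change has the configured sign in every
stratum whose true change exceeds four binomial standard errors at that
size — smaller configured changes (e.g. the 0.03-point decline for men
65-80) are not resolvable at any practical simulation size and are
checked for magnitude only through the coverage criterion.

## Known limitations

* The phenotype ignores inter-claim time gaps, so it cannot separate new
  episodes from ongoing care for one episode; "recurrence" means
  recurrent consultation, not clinically adjudicated recurrence.
* One diagnosis per claim is assumed (the billing rule of the source
  system); patients whose LBP is secondary to billed comorbidities are
  under-ascertained, and the package does not model that bias.
* Published tables are internally inconsistent in a few cells (relative
  risks and shares that disagree with their own rounded inputs at the
  last printed digit); consistency checks anchor on the reconcilable
  cells and tolerate ±1 integer point on endpoint percent variations.
* Mid-year age misclassifies patients near band boundaries by up to six
  months; with one-year bands in the denominators this is the best
  available convention, not an estimate of its own error.
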