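# lbpclaims

Claims-based surveillance of **recurrent low back pain (LBP)** from
administrative physician-billing data.

Single-payer health systems bill one ICD-9 diagnosis per physician visit.
That makes fee-for-service claims a practical instrument for watching how
often adults consult *repeatedly* for low back pain — without recall bias
and over long horizons — provided the "recurrent LBP patient" can be
defined operationally from claims alone. This package implements such a
phenotype and the descriptive statistics layer built on top of it, for
epidemiologists and health-services researchers working with
claims extracts of the form
`patient_id, sex, birth_year, service_date, icd9`.

## The phenotype and the statistics

A patient is a **claims-based recurrent LBP case** for index year *Y* when
their claims contain at least 3 diagnoses with an identical 3-digit ICD-9
stem from {721, 722, 724, 739}, on distinct service dates spanning fewer
than 365 days, with at least one of those dates in *Y*. The scan is a
sliding window over sorted distinct dates per (patient, stem) — provably
equivalent to enumerating all date triples, but linear after sorting.
A patient can be a case in several index years; each case-year is
attributed to the patient's sex and age band (mid-year age, bands
18-34 / 35-49 / 50-64 / 65-80 / 80+).

On top of the phenotype:

* **annual prevalence** per stratum, p̂ = k/n against population
  denominators, with **Wilson score** 99% intervals
  (centre (p̂ + z²/2n)/(1 + z²/n), half-width
  z·√(p̂(1−p̂)/n + z²/4n²)/(1 + z²/n));
* **male:female relative risks** RR = p̂₁/p̂₀ with Katz log-normal
  intervals exp(ln RR ± z·√(1/k₁ − 1/n₁ + 1/k₀ − 1/n₀));
* **trend summaries**: OLS slope of annual prevalence on calendar year,
  and endpoint percent variation 100·(p_last − p_first)/p_first;
* **Cherkin classification** of the 4-digit codes into seven mechanical-LBP
  categories (herniated disc, probably degenerative changes, spinal
  stenosis, possible instability, non-specific back aches, sequelae of
  previous back surgery, miscellaneous) with year-over-year frequency
  tables.

Because person-level claims registries are not publicly shareable, the
package ships a **synthetic claims generator** with exact ground truth:
cases receive qualifying same-stem claim clusters, background consulters
receive claims spaced wider than the recurrence window (so they can never
qualify), and true stratum prevalences are configurable — by default the
published Québec 2000/2007 stratified estimates.

## Worked example

```python
import lbpclaims as L

cfg = L.StudyConfig()                                  # 3 claims / 365 d / 99% CIs
scenario = L.scenario_from_prevalence_table(population=50_000)   # published strata as truth
claims, denoms, truth = L.generate(scenario, cfg, seed=7)
print("claims:", len(claims), " true case-years:", len(truth))

cohort = L.filter_cohort(claims, cfg)
cases, counts = L.phenotype_population(cohort, cfg)
print("flagged case-years:", len(cases))

prev = L.prevalence(counts, denoms, confidence=0.99)
row = prev.set_index(["year", "sex", "age_band"]).loc[(2000, "male", "35-49")]
print(f"male 35-49, 2000: {row.point:.2f}% [{row.lower:.2f} - {row.upper:.2f}]")
```

prints

```
claims: 155101  true case-years: 14797
flagged case-years: 14797
male 35-49, 2000: 2.07% [1.92 - 2.24]
```

The phenotype recovers the simulated truth exactly (14 797 of 14 797
case-years — background consulters are non-qualifying by construction),
and the recovered prevalence 2.07% sits inside the Wilson 99% interval of
the configured truth for this stratum (2.05%). A male:female risk ratio
for the same stratum:

```python
m = prev.set_index(["year", "sex", "age_band"]).loc[(2000, "male", "35-49")]
f = prev.set_index(["year", "sex", "age_band"]).loc[(2000, "female", "35-49")]
rr = L.relative_risk(int(m.cases), int(m.denominator), int(f.cases), int(f.denominator))
print(f"RR male:female 35-49, 2000: {rr.rr:.2f} [{rr.lower:.2f} - {rr.upper:.2f}]")
# RR male:female 35-49, 2000: 1.26 [1.12 - 1.42]
```

The same pipeline is available from the shell:

```sh
lbpclaims simulate --out-dir data --seed 7
lbpclaims phenotype --claims data/claims.csv --out cases.csv
lbpclaims prevalence --cases cases.csv --denominators data/denominators.csv --out table1.csv
lbpclaims report --claims data/claims.csv --denominators data/denominators.csv --out-dir report/
```

## Layout

| module | role |
| --- | --- |
| `lbpclaims.config` | `StudyConfig`, age-band definitions |
| `lbpclaims.io` | claims / denominator / config file I/O, row validation |
| `lbpclaims.cohort` | study-cohort filter (stems, window, minimum age) |
| `lbpclaims.phenotype` | sliding-window case finder, population phenotyping |
| `lbpclaims.categories` | Cherkin classification and frequency tables |
| `lbpclaims.stats` | Wilson intervals, prevalence, risk ratios, trends, report tables |
| `lbpclaims.simulate` | synthetic claims generator with exact ground truth |
| `lbpclaims.reference` | published Québec 2000/2007 surveillance values |
| `lbpclaims.cli` | `lbpclaims` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter choices,
and known limitations.
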