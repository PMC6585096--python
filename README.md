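# popseg

Expert-driven population segmentation of electronic-health-record cohorts,
with longitudinal evaluation of healthcare utilization and survival — plus a
calibrated synthetic cohort generator so the whole pipeline can be exercised
and validated without access to protected patient data.

Health systems increasingly plan services around *population segments*:
mutually exclusive groups of patients with similar care needs and expected
resource use. `popseg` implements a six-segment framework defined from
baseline-year data alone — **Mostly Healthy**, **Serious Acute**, **Stable
Chronic**, **Complex Chronic without Frequent Hospital Admissions**,
**Complex Chronic with Frequent Hospital Admissions** (≥ 3 inpatient
admissions in the 12-month baseline window, a proxy for high-cost users),
and **End of Life** — and evaluates whether baseline segment membership
predicts utilization and mortality over the following three years.

## What it computes

For a cohort of adults (age ≥ 21 in the baseline year, ≥ 1 baseline
encounter) with a patient table and a dated encounter table (ED attendances,
specialist outpatient clinic [SOC] attendances, inpatient admissions):

* **Segmentation** — a precedence-ordered rule engine
  (`SegmentClassifier`, a scikit-learn estimator) assigns every patient
  exactly one segment from condition flags and the baseline admission count.
* **Survival** — follow-up runs from entry (2013-01-01) to study end
  (2015-12-31); a patient alive throughout is censored at 1094 days.
  Per-segment Kaplan–Meier curves S(t) = Π(1 − dᵢ/nᵢ) and the K-group
  log-rank test.
* **Utilization** — per-segment totals, rates per 1000 patient-days
  (rate = total × 1000 / Σ follow-up days) and, per outcome, an NB2
  negative binomial regression

  log E[Yᵢ] = log(tᵢ) + β₀ + β_seg + β·xᵢ,  Var[Yᵢ] = μᵢ + α μᵢ²

  with survival time tᵢ as exposure, Mostly Healthy as the reference
  segment and adjustment for age, gender, ethnicity and baseline-year
  utilization. Exponentiated segment coefficients are incidence rate ratios
  (IRRs) with Wald 95% CIs, and all 15 pairwise segment contrasts are
  tested by Wald chi-square.
* **Synthetic cohorts** — `CohortGenerator` draws seeded cohorts whose
  segment mix, demographics, overdispersed follow-up counts and
  piecewise-exponential survival match a configurable calibration, and
  whose baseline encounters *satisfy* each patient's segment definition, so
  the classifier reproduces the generator's ground truth exactly.

## Worked example

```python
from popseg import GeneratorConfig, run_pipeline

bundle = run_pipeline(GeneratorConfig(n_patients=20_000, seed=7), "out/")
print(bundle.table1.loc["Total (%)"])
print(bundle.table3[bundle.table3.outcome == "No. of ED visits"])
print(bundle.log_rank)
```

prints (abridged):

```
Mostly Healthy                                           11,684 (58.4%)
Serious Acute                                             4,906 (24.5%)
Stable Chronic                                             1,082 (5.4%)
Complex Chronic without Frequent Hospital Admissions      2,209 (11.0%)
Complex Chronic with Frequent Hospital Admissions             82 (0.4%)
End of Life                                                   37 (0.2%)

         outcome                                            segment       irr          ci95       p
No. of ED visits                                      Serious Acute      2.12  (1.89, 2.38) < 0.001
No. of ED visits                                     Stable Chronic      2.35  (1.83, 3.02) < 0.001
No. of ED visits  Complex Chronic without Frequent Hosp. Admissions      5.06  (4.16, 6.14) < 0.001
No. of ED visits     Complex Chronic with Frequent Hosp. Admissions     24.30 (9.92, 59.56) < 0.001
No. of ED visits                                        End of Life      3.70 (1.32, 10.33)   0.013

log-rank: {'statistic': 694.5, 'df': 5, 'p_value': 7.5e-148}
```

The first block is the segment composition of the simulated cohort (counts
and column percentages); the IRR column says, e.g., that frequent
hospital admitters attend the ED at ~24 times the Mostly Healthy rate per
day of follow-up after adjustment; the log-rank test rejects equality of
the six survival curves. (In a fully generated cohort the adjusted IRRs
differ from the raw rate ratios because baseline utilization — part of each
segment's definition — is itself in the model.)

The same pipeline is scriptable from a shell:

```bash
popseg simulate --n 20000 --seed 7 --out data/
popseg segment --patients data/patients.csv --encounters data/encounters.csv --out segments.csv
popseg run --n 20000 --seed 7 --out out/
```

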