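# Methods

## The segmentation framework

Patients are partitioned, using baseline-year (2012) data only, into six
mutually exclusive segments. Each segment has a predicate over a patient's
condition flags and baseline inpatient admission count; a patient receives
the first segment, in a configurable precedence order, whose predicate
holds. Defaults:

| precedence | segment | predicate |
|---|---|---|
| 1 | End of Life | end-of-life condition flag |
| 2 | Complex Chronic with Frequent Hospital Admissions | ≥ 2 recognized chronic conditions and ≥ 3 admissions in the baseline window |
| 3 | Complex Chronic without Frequent Hospital Admissions | ≥ 2 recognized chronic conditions, < 3 admissions |
| 4 | Serious Acute | serious-acute condition flag |
| 5 | Stable Chronic | ≥ 1 recognized chronic condition |
| 6 | Mostly Healthy | always (catch-all, must be last) |

Design choices where the framework is genuinely open:

* **Precedence.** Non-overlap requires a tie-break; we order predicates by
  descending severity (End of Life first). The order is a `SegmentRuleSet`
  parameter; a property test verifies that patients satisfying a single
  predicate are order-invariant.
* **Baseline window.** The 2012 calendar year, closed on both ends, rather
  than a rolling 365-day lookback per encounter — segment membership is a
  baseline-year attribute. Configurable.
* **Stable vs Complex Chronic.** Distinguished by the count of recognized
  chronic conditions (1 vs ≥ 2). Clinical code lists are site-specific, so
  the engine takes a category vocabulary; a default of eight common chronic
  categories (diabetes, hypertension, hyperlipidemia, ischemic heart
  disease, stroke, COPD/asthma, chronic kidney disease, heart failure)
  ships for simulation. Conditions outside the vocabulary are ignored.
* **Frequent admissions.** ≥ 3 inpatient admissions in the 12-month
  baseline window (threshold configurable); ED and SOC contacts never
  count toward it.

Eligibility: age ≥ 21 in 2012 and at least one 2012 encounter of any kind.

## Survival

Entry is 2013-01-01; study end is 2015-12-31, i.e. a 1094-day horizon.
Death on or before the study end gives `time = death − entry` days with an
event; otherwise time is exactly 1094 days, censored. Deaths recorded after
the study end are censored at 1094 (the censoring rule refers only to the
study window). A death on the entry date itself gets time 0 with an event
and is retained; in count models such patients receive a one-day exposure
floor so the log-offset stays finite. Patients who died before entry never
enter follow-up; the pipeline drops them and logs the count.

Kaplan–Meier estimation and the K-group log-rank test are computed via
lifelines (ties aggregated per day; censored-at-event-time patients remain
at risk at that time). The test suite cross-checks both against naive
risk-set enumerations.

## Count models

For each outcome (ED, SOC, inpatient admissions 2013–2015) we fit NB2
maximum likelihood: log link, log(survival days) offset, Mostly Healthy
reference, adjusted for age (continuous years by default; the standard
bands 21–30 … >90 as an option), gender, ethnicity and baseline-year
utilization. "Past utilization" enters as all three 2012 counts — the
conservative reading; a switch disables it. Overdispersion α is estimated
jointly with the coefficients; Wald 95% CIs are exp(β ± 1.96·SE).

Numerical details: the NB2 likelihood is optimized from a Poisson-GLM warm
start with a method-of-moments α; optimizers fall back newton → BFGS →
Nelder–Mead, and a fit whose dispersion collapses to the Poisson boundary
(singular NB2 Hessian) is reported as the Poisson MLE with α = 0.
Non-convergence is flagged in the result, never hidden. A rank-deficient
design raises an error rather than fitting a pseudo-inverse.

Pairwise segment comparisons default to a 1-df Wald contrast of coefficient
equality (a pair differs by one constraint); a 2-df joint test of both
coefficients against the reference is available as an option, since either
construction is defensible. All 15 raw p-values are reported; a Bonferroni
toggle exists but is off by default.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
defaults calibrated to the published cohort: segment proportions
58.8 / 24.5 / 5.3 / 10.7 / 0.5 / 0.2 %, per-segment age means/SDs, gender
and ethnicity fractions, follow-up rates per 1000 patient-days per segment
and outcome, and yearly survival probabilities (End of Life
74.6 / 64.6 / 58.2 %; frequent admitters 81.7 / 71.0 / 62.6 %; the
remaining segments set inside the published "> 95 / > 93 / > 90 %"
envelopes at 99.5/99.0/98.5, 98.5/97.5/96.5, 99.2/98.6/98.0 and
96.0/94.0/92.0 %).

* **Baseline encounters** are drawn to *satisfy* the segment definitions —
  frequent admitters get 3 + Poisson admissions, everyone else is capped at
  2; every patient gets ≥ 1 baseline encounter — so the rule engine
  reproduces the generator's ground truth with probability 1. This
  round-trip is the module's testability anchor. Mean baseline counts per
  segment are not printed anywhere; defaults were chosen to reproduce the
  published medians and any-use percentages.
* **Survival** is piecewise exponential with knots at days 365/730/1094,
  rates solved per interval from the configured yearly survival — the
  simplest law that reproduces all three printed yearly rates.
* **Follow-up counts** are NB2 via a gamma–Poisson mixture with mean
  (rate/1000) × realized survived days, so nobody accrues encounters after
  death. Default α per outcome (ED 5.0, SOC 3.5, admissions 5.0) is a
  method-of-moments match to the published per-segment mean (SD) pairs.
  Outcomes are generated independently given segment; within-patient
  correlation across ED/SOC/admissions is not emulated (no published
  calibration target exists for it), so tests exercise marginal structure
  only.
* **Randomness**: one master seed feeds named sub-streams (segment, age,
  gender, ethnicity, conditions, baseline, baseline dates, survival,
  follow-up counts, follow-up dates) spawned in a fixed order, so the same
  seed is byte-reproducible and stages do not perturb one another.

What the generator does *not* emulate: ICD-coded diagnosis streams,
comorbidity correlation beyond segment membership, seasonal encounter
patterns, or costs. Passing tests therefore demonstrate the pipeline's
correctness and calibration on data with the assumed structure, not
performance of the framework on any real population.

## Validation experiments and problem sizes

* **IRR recovery** — six equal segments, n = 60,000, true multipliers set
  to the published adjusted-IRR columns, balanced covariates with zero true
  effect, full 1094-day exposure, NB2 α = 1. The reference-segment rate is
  one expected event per follow-up (≈ 0.91/1000 patient-days), chosen by
  power analysis so the reference log-rate contributes well under 2% SE to
  each IRR; at the very low empirical reference rates the recovery
  experiment would be dominated by reference noise rather than model
  behavior. Estimates land within 5% of the generating multipliers.
* **KM recovery** — n = 2,000 exponential survival times with
  S(1094) = 0.582, administratively censored at day 1094.
* **Repeated-cohort properties** — 100 cohorts of n = 20,000 for IRR bias
  (< 2%) and CI coverage (within [90%, 98%]); 1,000 null replicates for
  log-rank type-I error; 500 for pairwise-contrast type-I error. These
  sizes keep the full suite around a minute on one CPU while leaving the
  Monte-Carlo error well inside each asserted tolerance.

## Known limitations

* The chronic-condition vocabulary and the serious-acute / end-of-life
  flags abstract away clinical code lists; applying the engine to real data
  requires mapping local codes to these categories first.
* The NB2 adjusted model treats segment effects as time-constant over the
  three follow-up years and ignores within-patient event clustering beyond
  the NB dispersion.
* Rates per 1000 patient-days use survival time as the denominator, so a
  segment's rate conflates utilization intensity with mortality-shortened
  exposure — the same convention as the printed tables, but worth keeping
  in mind when comparing high-mortality segments.
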