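"""Seeded synthetic EHR cohort generator.

Produces a patient table, an encounter table and the ground-truth segment of
every patient, with the statistical structure the downstream analysis
assumes:

* segment membership drawn from configured proportions;
* demographics drawn from per-segment marginals (ages truncated to 21-100);
* baseline-year (2012) encounters generated to *satisfy* each patient's
  assigned segment definition — a frequent-admitter receives at least three
  2012 inpatient admissions, every other patient at most two — so that the
  rule-based classifier reproduces the ground truth exactly (round-trip
  property);
* follow-up (2013-2015) death times from a piecewise-exponential model with
  knots at days 365/730/1094 whose yearly survival matches configuration;
* follow-up encounter counts from an NB2 (gamma-Poisson) law with mean
  proportional to each patient's realized survived days, so no encounters
  fall after death.

All randomness flows from one master seed through named sub-streams spawned
in a fixed order (segment, age, gender, ethnicity, conditions, baseline,
baseline-dates, survival, follow-up counts, follow-up dates), so draws for
one stage are unaffected by changes to another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig
from .errors import DataIntegrityError
from .segments import (
    DEFAULT_CHRONIC_VOCABULARY,
    ENCOUNTER_KINDS,
    ETHNICITIES,
    SEGMENT_ORDER,
)

BASELINE_START = pd.Timestamp("2012-01-01")
BASELINE_DAYS = 366  # 2012 is a leap year
ENTRY_DATE = pd.Timestamp("2013-01-01")
STUDY_END = pd.Timestamp("2015-12-31")
FOLLOWUP_DAYS = 1094  # (2015-12-31) - (2013-01-01) in days
YEAR_KNOTS = (365, 730, 1094)

_STREAMS = ["segment", "age", "gender", "ethnicity", "conditions",
            "baseline", "baseline_dates", "survival", "followup", "followup_dates"]

PATIENT_COLUMNS = ["patient_id", "age_2012", "gender", "ethnicity", "death_date",
                   "chronic_conditions", "serious_acute", "end_of_life_condition"]
ENCOUNTER_COLUMNS = ["patient_id", "date", "kind"]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _empty_patients() -> pd.DataFrame:
    df = pd.DataFrame(columns=PATIENT_COLUMNS)
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


def _empty_encounters() -> pd.DataFrame:
    df = pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    return df


def piecewise_exponential_rates(yearly_survival: tuple[float, float, float]) -> np.ndarray:
    """Hazard per day on [0,365), [365,730), [730,1094] matching the yearly
    survival probabilities at the knots."""
    s1, s2, s3 = yearly_survival
    spans = np.diff((0,) + YEAR_KNOTS)
    surv = np.array([1.0, s1, s2, s3])
    return -np.log(surv[1:] / surv[:-1]) / spans


def sample_piecewise_exponential(
    yearly_survival: tuple[float, float, float],
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw continuous death times; times beyond day 1094 come back as +inf
    (the patient outlives the study window)."""
    s1, s2, s3 = yearly_survival
    rates = piecewise_exponential_rates(yearly_survival)
    u = rng.uniform(size=size)
    t = np.full(size, np.inf)
    bounds = [(s1, 1.0, 0.0, rates[0]), (s2, s1, 365.0, rates[1]), (s3, s2, 730.0, rates[2])]
    for lo, hi, offset, rate in bounds:
        mask = (u >= lo) & (u < hi) & (rate > 0)
        if mask.any():
            t[mask] = offset + (-np.log(u[mask] / hi)) / rate
    # u == 1 exactly (probability zero but possible in floating point)
    t[u >= 1.0] = 0.0
    return t


def _nb2_counts(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """NB2 draws via the gamma-Poisson mixture; alpha=0 degenerates to Poisson."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def _encounter_rows(patient_ids: np.ndarray, counts: np.ndarray, kind: str,
                    start: pd.Timestamp, window_days: np.ndarray | int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Expand per-patient counts into dated encounter rows with uniform dates."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total == 0:
        return _empty_encounters()
    ids = np.repeat(patient_ids, counts)
    if np.isscalar(window_days):
        days = rng.integers(0, window_days, size=total)
    else:
        spans = np.repeat(np.asarray(window_days), counts)
        days = np.floor(rng.uniform(size=total) * spans).astype(np.int64)
    return pd.DataFrame({
        "patient_id": ids,
        "date": start + pd.to_timedelta(days, unit="D"),
        "kind": kind,
    })


class CohortGenerator:
    """Synthetic cohort generator driven by a :class:`GeneratorConfig`.

    Examples
    --------
    >>> gen = CohortGenerator(GeneratorConfig(n_patients=1000, seed=7))
    >>> patients, encounters, true_segments = gen.generate_cohort()
    """

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config if config is not None else GeneratorConfig()
        self.config.validate()

    # --- baseline -----------------------------------------------------------

    def generate_cohort(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
        """Generate the baseline cohort.

        Returns
        -------
        patients : DataFrame with :data:`PATIENT_COLUMNS` (death_date all NaT
            until :meth:`sample_followup_outcomes` is applied).
        encounters : DataFrame of 2012 encounters.
        true_segments : Series patient_id -> segment label string.
        """
        cfg = self.config
        n = cfg.n_patients
        rngs = _rngs(cfg.seed)
        if n == 0:
            return _empty_patients(), _empty_encounters(), pd.Series(dtype=object, name="segment")

        props = np.array([cfg.segment_proportions[s] for s in SEGMENT_ORDER])
        seg_idx = rngs["segment"].choice(len(SEGMENT_ORDER), size=n, p=props)
        patient_ids = np.array([f"P{i:07d}" for i in range(n)])

        ages = np.empty(n, dtype=np.int64)
        male = np.zeros(n, dtype=bool)
        eth_idx = np.empty(n, dtype=np.int64)
        male_p = np.empty(n)
        for k, seg in enumerate(SEGMENT_ORDER):
            mask = seg_idx == k
            m = int(mask.sum())
            if m == 0:
                continue
            demo = cfg.demographic_marginals[seg]
            lo, hi = 21, 100
            sd = max(demo["age_sd"], 1e-12)
            a, b = (lo - demo["age_mean"]) / sd, (hi - demo["age_mean"]) / sd
            draw = stats.truncnorm.rvs(a, b, loc=demo["age_mean"], scale=sd,
                                       size=m, random_state=rngs["age"])
            ages[mask] = np.clip(np.rint(draw), lo, hi).astype(np.int64)
            male_p[mask] = demo["male_fraction"]
            fr = np.asarray(demo["ethnicity_fractions"], dtype=float)
            eth_idx[mask] = rngs["ethnicity"].choice(len(ETHNICITIES), size=m, p=fr / fr.sum())
        male = rngs["gender"].uniform(size=n) < male_p

        chronic, serious, eol = self._draw_condition_flags(seg_idx, rngs["conditions"])
        encounters = self._draw_baseline_encounters(
            patient_ids, seg_idx, rngs["baseline"], rngs["baseline_dates"])

        patients = pd.DataFrame({
            "patient_id": patient_ids,
            "age_2012": ages,
            "gender": np.where(male, "male", "female"),
            "ethnicity": np.array(ETHNICITIES, dtype=object)[eth_idx],
            "death_date": pd.NaT,
            "chronic_conditions": chronic,
            "serious_acute": serious,
            "end_of_life_condition": eol,
        })
        true_segments = pd.Series(
            np.array(SEGMENT_ORDER, dtype=object)[seg_idx],
            index=pd.Index(patient_ids, name="patient_id"), name="segment")
        return patients, encounters, true_segments

    def _draw_condition_flags(self, seg_idx, rng):
        """Condition counts by segment rule: Mostly Healthy 0; Stable Chronic
        exactly 1; Serious Acute at most 1; the Complex segments at least 2;
        End of Life unconstrained (its flag takes precedence)."""
        n = seg_idx.shape[0]
        vocab = np.array(DEFAULT_CHRONIC_VOCABULARY, dtype=object)
        nv = len(vocab)
        seg = np.array(SEGMENT_ORDER, dtype=object)[seg_idx]

        k = np.zeros(n, dtype=np.int64)
        k[seg == "STABLE_CHRONIC"] = 1
        sa_mask = seg == "SERIOUS_ACUTE"
        k[sa_mask] = rng.uniform(size=int(sa_mask.sum())) < 0.3
        complex_mask = np.isin(seg, ["COMPLEX_CHRONIC_NO_FREQ", "COMPLEX_CHRONIC_FREQ"])
        k[complex_mask] = 2 + rng.poisson(1.0, size=int(complex_mask.sum()))
        eol_mask = seg == "END_OF_LIFE"
        k[eol_mask] = rng.poisson(2.0, size=int(eol_mask.sum()))
        k = np.minimum(k, nv)

        # per-patient random permutation of the vocabulary; take the first k
        order = np.argsort(rng.uniform(size=(n, nv)), axis=1)
        chronic = np.empty(n, dtype=object)
        for i in range(n):
            chronic[i] = tuple(sorted(vocab[order[i, :k[i]]]))

        serious = sa_mask.copy()
        serious[eol_mask] = rng.uniform(size=int(eol_mask.sum())) < 0.2
        return chronic, serious, eol_mask

    def _draw_baseline_encounters(self, patient_ids, seg_idx, rng, rng_dates):
        cfg = self.config
        n = seg_idx.shape[0]
        seg_names = np.array(SEGMENT_ORDER, dtype=object)[seg_idx]
        freq_mask = seg_names == "COMPLEX_CHRONIC_FREQ"

        counts: dict[str, np.ndarray] = {}
        for kind in ENCOUNTER_KINDS:
            means = np.array([cfg.baseline_2012_rates[kind][s] for s in SEGMENT_ORDER])
            mu = means[seg_idx]
            c = rng.poisson(mu)
            if kind == "INPATIENT":
                # enforce the segment definitions exactly: frequent admitters
                # get >= 3 admissions, everyone else <= 2
                c = np.minimum(c, 2)
                excess = np.maximum(mu[freq_mask] - 3.0, 0.0)
                c[freq_mask] = 3 + rng.poisson(excess)
            counts[kind] = c
        # inclusion requires at least one 2012 encounter
        total = sum(counts.values())
        counts["SOC"] = counts["SOC"] + (total == 0)

        frames = [_encounter_rows(patient_ids, counts[kind], kind,
                                  BASELINE_START, BASELINE_DAYS, rng_dates)
                  for kind in ENCOUNTER_KINDS]
        enc = pd.concat([f for f in frames if len(f)], ignore_index=True) \
            if any(len(f) for f in frames) else _empty_encounters()
        return enc.sort_values(["patient_id", "date", "kind"], ignore_index=True)

    # --- follow-up ----------------------------------------------------------

    def sample_followup_outcomes(
        self, patients: pd.DataFrame, true_segments: pd.Series,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Draw 2013-2015 deaths and encounters for an existing cohort.

        Returns ``(followup_encounters, patients_with_death_dates)``; the
        input patient table is not modified.
        """
        cfg = self.config
        rngs = _rngs(cfg.seed)
        if len(patients) == 0:
            return _empty_encounters(), patients.copy()
        missing = set(patients["patient_id"]) - set(true_segments.index)
        if missing:
            raise DataIntegrityError(
                f"{len(missing)} patients have no segment (e.g. {sorted(missing)[:3]})")
        seg_names = true_segments.loc[patients["patient_id"]].to_numpy()
        seg_idx = np.array([SEGMENT_ORDER.index(s) for s in seg_names])
        n = len(patients)

        # death times, one segment at a time (shared survival stream)
        t = np.full(n, np.inf)
        for k, seg in enumerate(SEGMENT_ORDER):
            mask = seg_idx == k
            if mask.any():
                t[mask] = sample_piecewise_exponential(
                    tuple(cfg.yearly_survival[seg]), int(mask.sum()), rngs["survival"])
        event = t <= FOLLOWUP_DAYS
        time_days = np.where(event, np.floor(t), FOLLOWUP_DAYS).astype(np.int64)

        out_patients = patients.copy()
        death = pd.Series(pd.NaT, index=patients.index, dtype="datetime64[ns]")
        death[event] = ENTRY_DATE + pd.to_timedelta(time_days[event], unit="D")
        out_patients["death_date"] = death

        survived = np.maximum(time_days, 1)  # exposure floor of one day
        pids = patients["patient_id"].to_numpy()
        frames = []
        for kind in ENCOUNTER_KINDS:
            rates = np.array([cfg.followup_rates[kind][s] for s in SEGMENT_ORDER])
            mu = rates[seg_idx] / 1000.0 * survived
            c = _nb2_counts(mu, cfg.dispersion[kind], rngs["followup"])
            frames.append(_encounter_rows(pids, c, kind, ENTRY_DATE, survived,
                                          rngs["followup_dates"]))
        enc = pd.concat([f for f in frames if len(f)], ignore_index=True) \
            if any(len(f) for f in frames) else _empty_encounters()
        return enc.sort_values(["patient_id", "date", "kind"], ignore_index=True), out_patients

    # --- one-call convenience ----------------------------------------------

    def generate(self) -> dict:
        """Baseline + follow-up in one call.

        Returns a dict with keys ``patients`` (death dates applied),
        ``encounters`` (2012 through 2015) and ``true_segments``.
        """
        patients, baseline, true_segments = self.generate_cohort()
        followup, patients = self.sample_followup_outcomes(patients, true_segments)
        parts = [f for f in (baseline, followup) if len(f)]
        encounters = (pd.concat(parts, ignore_index=True)
                      .sort_values(["patient_id", "date", "kind"], ignore_index=True)
                      if parts else _empty_encounters())
        return {"patients": patients, "encounters": encounters,
                "true_segments": true_segments}


def generate_cohort(config: GeneratorConfig):
    """Functional wrapper over :meth:`CohortGenerator.generate_cohort`."""
    return CohortGenerator(config).generate_cohort()


def sample_followup_outcomes(patients, true_segments, config: GeneratorConfig):
    """Functional wrapper over :meth:`CohortGenerator.sample_followup_outcomes`."""
    return CohortGenerator(config).sample_followup_outcomes(patients, true_segments)
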