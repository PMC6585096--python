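"""Survival-time construction, Kaplan-Meier estimation and the log-rank test.

Follow-up runs from a fixed entry date (2013-01-01) to a fixed study end
(2015-12-31).  A patient who dies on or before the study end contributes
``death_date - entry`` days with an event; everyone else is administratively
censored at 1094 days (the entry-to-study-end span).  Deaths recorded after
the study end are, by the same rule, censored at 1094 days.

Estimation is the classical product-limit estimator and the K-group
log-rank chi-square test, computed via lifelines.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import DataIntegrityError, EstimationError, ConfigError

logger = logging.getLogger(__name__)

ENTRY_DATE = pd.Timestamp("2013-01-01")
STUDY_END = pd.Timestamp("2015-12-31")
CENSOR_DAYS = int((STUDY_END - ENTRY_DATE).days)  # 1094


def compute_survival_time(death_date,
                          entry: pd.Timestamp = ENTRY_DATE,
                          study_end: pd.Timestamp = STUDY_END) -> tuple[int, int]:
    """Follow-up days and event indicator for one patient.

    Returns ``(time_days, event)`` with ``event=1`` for a death on or before
    ``study_end`` and ``event=0`` (time = full span) otherwise.  A death
    date before ``entry`` is an eligibility violation.
    """
    horizon = int((study_end - entry).days)
    if death_date is None or pd.isna(death_date):
        return horizon, 0
    death_date = pd.Timestamp(death_date)
    if death_date < entry:
        raise DataIntegrityError(
            f"death_date {death_date.date()} precedes follow-up entry {entry.date()}")
    if death_date > study_end:
        return horizon, 0
    return int((death_date - entry).days), 1


def build_survival_table(patients: pd.DataFrame,
                         entry: pd.Timestamp = ENTRY_DATE,
                         study_end: pd.Timestamp = STUDY_END) -> pd.DataFrame:
    """Per-patient survival records for a cohort.

    Patients who died before the entry date never enter follow-up; they are
    dropped with a logged count.  Returns columns patient_id, time_days,
    event.
    """
    death = pd.to_datetime(patients["death_date"])
    pre_entry = death.notna() & (death < entry)
    if pre_entry.any():
        logger.info("excluding %d patients deceased before follow-up entry",
                    int(pre_entry.sum()))
    kept = patients.loc[~pre_entry]
    death = pd.to_datetime(kept["death_date"])
    horizon = int((study_end - entry).days)
    event = (death.notna() & (death <= study_end)).astype(int)
    time_days = np.where(event == 1, (death - entry).dt.days, horizon)
    return pd.DataFrame({"patient_id": kept["patient_id"].to_numpy(),
                         "time_days": time_days.astype(np.int64),
                         "event": event.to_numpy()})


@dataclasses.dataclass
class KMCurve:
    """A fitted product-limit curve: distinct event times, the survival
    probability just after each, and the number at risk just before each."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation of S(t)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate from (time_days, event) records.

    Ties are aggregated per day; a patient censored at an event time is
    still at risk at that time (the standard convention).
    """
    if len(records) == 0:
        raise EstimationError("cannot estimate a survival curve from no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], event_observed=records["event"])
    table = kmf.event_table
    events = table[table["observed"] > 0]
    times = events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]].to_numpy()
    at_risk = events["at_risk"].to_numpy(dtype=np.int64)
    return KMCurve(event_times=times, survival=surv, at_risk=at_risk)


def survival_at(curve: KMCurve, t: float) -> float:
    """Functional wrapper over :meth:`KMCurve.survival_at`."""
    return curve.survival_at(t)


@dataclasses.dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def log_rank_test(records: pd.DataFrame, labels: pd.Series) -> LogRankResult:
    """K-group log-rank chi-square test (df = K - 1).

    ``labels`` maps patient_id -> group; every record must be labeled and
    every group nonempty.
    """
    groups = labels.reindex(records["patient_id"]).to_numpy()
    if pd.isna(groups).any():
        n_bad = int(pd.isna(groups).sum())
        raise DataIntegrityError(f"{n_bad} survival records have no group label")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ConfigError("log-rank test needs at least two nonempty groups")
    res = multivariate_logrank_test(records["time_days"], groups, records["event"])
    return LogRankResult(statistic=float(res.test_statistic),
                         df=len(uniq) - 1,
                         p_value=float(res.p_value))
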