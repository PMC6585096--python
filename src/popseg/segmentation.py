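"""Rule-based assignment of patients to the six population segments.

Classification uses baseline-year (2012) data only and is driven by a
precedence-ordered rule set: each segment has a predicate over a patient's
condition flags and baseline inpatient admission count, and the patient
receives the first segment in the precedence order whose predicate holds.
The catch-all Mostly Healthy predicate is always true and must come last,
which makes the assignment a total function — every eligible patient gets
exactly one label.

Default predicates (all thresholds configurable):

* END_OF_LIFE          — end-of-life condition flag set;
* COMPLEX_CHRONIC_FREQ — >= 2 recognized chronic conditions and >= 3
  baseline inpatient admissions;
* COMPLEX_CHRONIC_NO_FREQ — >= 2 recognized chronic conditions, < 3
  admissions;
* SERIOUS_ACUTE        — serious-acute condition flag set;
* STABLE_CHRONIC       — >= 1 recognized chronic condition;
* MOSTLY_HEALTHY       — always.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataIntegrityError
from .segments import DEFAULT_CHRONIC_VOCABULARY, DEFAULT_PRECEDENCE, SEGMENT_ORDER

BASELINE_WINDOW = (pd.Timestamp("2012-01-01"), pd.Timestamp("2012-12-31"))
MIN_AGE = 21


@dataclasses.dataclass
class SegmentRuleSet:
    """Configurable content of the six segment definitions.

    ``chronic_condition_categories`` is the recognized chronic-disease
    vocabulary (conditions outside it are ignored when counting);
    ``frequent_admission_threshold`` is the frequent-admitter cut-off (three
    or more admissions in the 12-month baseline window);
    ``complex_min_chronic_count`` separates Stable Chronic (fewer) from the
    Complex Chronic segments (at least this many).
    """

    chronic_condition_categories: frozenset = dataclasses.field(
        default_factory=lambda: frozenset(DEFAULT_CHRONIC_VOCABULARY))
    complex_min_chronic_count: int = 2
    frequent_admission_threshold: int = 3
    lookback_days: int = 365
    precedence: tuple = tuple(DEFAULT_PRECEDENCE)
    baseline_window: tuple = BASELINE_WINDOW

    def __post_init__(self) -> None:
        self.chronic_condition_categories = frozenset(self.chronic_condition_categories)
        self.precedence = tuple(self.precedence)
        self.validate()

    def validate(self) -> None:
        if self.frequent_admission_threshold < 1:
            raise ConfigError("frequent_admission_threshold must be >= 1")
        if self.complex_min_chronic_count < 1:
            raise ConfigError("complex_min_chronic_count must be >= 1")
        if sorted(self.precedence) != sorted(SEGMENT_ORDER):
            raise ConfigError(
                f"precedence must be a permutation of the six segments, got {self.precedence}")
        if self.precedence[-1] != "MOSTLY_HEALTHY":
            raise ConfigError("precedence must end with MOSTLY_HEALTHY (the catch-all)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "chronic_condition_categories": sorted(self.chronic_condition_categories),
            "complex_min_chronic_count": self.complex_min_chronic_count,
            "frequent_admission_threshold": self.frequent_admission_threshold,
            "lookback_days": self.lookback_days,
            "precedence": list(self.precedence),
            "baseline_window": [str(d.date()) for d in self.baseline_window],
        }, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentRuleSet":
        d = yaml.safe_load(Path(path).read_text())
        if "baseline_window" in d:
            d["baseline_window"] = tuple(pd.Timestamp(x) for x in d["baseline_window"])
        if "chronic_condition_categories" in d:
            d["chronic_condition_categories"] = frozenset(d["chronic_condition_categories"])
        if "precedence" in d:
            d["precedence"] = tuple(d["precedence"])
        return cls(**d)


def filter_eligible(patients: pd.DataFrame, encounters: pd.DataFrame,
                    min_age: int = MIN_AGE,
                    baseline_window: tuple = BASELINE_WINDOW) -> pd.DataFrame:
    """Inclusion filter: adults (age >= 21 in 2012) with at least one
    baseline-year encounter."""
    if patients["age_2012"].isna().any():
        n_bad = int(patients["age_2012"].isna().sum())
        raise DataIntegrityError(f"{n_bad} patients are missing age_2012")
    lo, hi = baseline_window
    dates = pd.to_datetime(encounters["date"])
    in_window = encounters.loc[(dates >= lo) & (dates <= hi), "patient_id"]
    has_baseline = patients["patient_id"].isin(set(in_window))
    return patients.loc[(patients["age_2012"] >= min_age) & has_baseline].reset_index(drop=True)


def count_admissions_in_window(encounters: pd.DataFrame, window: tuple) -> int:
    """Inpatient admissions for one patient's encounters within the closed
    window; ED and SOC contacts never count."""
    if len(encounters) == 0:
        return 0
    lo, hi = window
    dates = pd.to_datetime(encounters["date"])
    mask = (encounters["kind"] == "INPATIENT") & (dates >= lo) & (dates <= hi)
    return int(mask.sum())


def _chronic_counts(patients: pd.DataFrame, recognized: frozenset) -> np.ndarray:
    return np.array([len(recognized.intersection(c))
                     for c in patients["chronic_conditions"]], dtype=np.int64)


def _admission_counts(patients: pd.DataFrame, encounters: pd.DataFrame,
                      window: tuple) -> np.ndarray:
    lo, hi = window
    dates = pd.to_datetime(encounters["date"])
    mask = (encounters["kind"] == "INPATIENT") & (dates >= lo) & (dates <= hi)
    per_patient = encounters.loc[mask].groupby("patient_id").size()
    return (patients["patient_id"].map(per_patient).fillna(0).astype(np.int64).to_numpy())


class SegmentClassifier(BaseEstimator):
    """Precedence-ordered rule classifier over baseline patient features.

    A scikit-learn style estimator: hyperparameters mirror
    :class:`SegmentRuleSet`, :meth:`fit` validates them, and
    :meth:`predict` labels a cohort.  The classifier is deterministic and
    needs no training data; ``fit`` exists for pipeline compatibility.
    """

    def __init__(self, chronic_condition_categories=frozenset(DEFAULT_CHRONIC_VOCABULARY),
                 complex_min_chronic_count=2, frequent_admission_threshold=3,
                 lookback_days=365, precedence=tuple(DEFAULT_PRECEDENCE),
                 baseline_window=BASELINE_WINDOW):
        self.chronic_condition_categories = chronic_condition_categories
        self.complex_min_chronic_count = complex_min_chronic_count
        self.frequent_admission_threshold = frequent_admission_threshold
        self.lookback_days = lookback_days
        self.precedence = precedence
        self.baseline_window = baseline_window

    @classmethod
    def from_rules(cls, rules: SegmentRuleSet) -> "SegmentClassifier":
        return cls(**{f.name: getattr(rules, f.name) for f in dataclasses.fields(rules)})

    def fit(self, X=None, y=None) -> "SegmentClassifier":
        """Validate the rule set; no parameters are learned."""
        self.rules_ = SegmentRuleSet(
            chronic_condition_categories=self.chronic_condition_categories,
            complex_min_chronic_count=self.complex_min_chronic_count,
            frequent_admission_threshold=self.frequent_admission_threshold,
            lookback_days=self.lookback_days,
            precedence=self.precedence,
            baseline_window=self.baseline_window)
        return self

    def predict(self, patients: pd.DataFrame, encounters: pd.DataFrame) -> pd.Series:
        """Label every patient; returns a Series patient_id -> segment."""
        if not hasattr(self, "rules_"):
            self.fit()
        rules = self.rules_
        if patients["patient_id"].duplicated().any():
            dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise DataIntegrityError(f"duplicate patient_id {dup!r}")
        chronic = _chronic_counts(patients, rules.chronic_condition_categories)
        admissions = _admission_counts(patients, encounters, rules.baseline_window)
        is_complex = chronic >= rules.complex_min_chronic_count
        predicates = {
            "END_OF_LIFE": patients["end_of_life_condition"].to_numpy(bool),
            "COMPLEX_CHRONIC_FREQ": is_complex
                & (admissions >= rules.frequent_admission_threshold),
            "COMPLEX_CHRONIC_NO_FREQ": is_complex
                & (admissions < rules.frequent_admission_threshold),
            "SERIOUS_ACUTE": patients["serious_acute"].to_numpy(bool),
            "STABLE_CHRONIC": chronic >= 1,
            "MOSTLY_HEALTHY": np.ones(len(patients), dtype=bool),
        }
        labels = np.select([predicates[s] for s in rules.precedence],
                           [np.full(len(patients), s, dtype=object)
                            for s in rules.precedence],
                           default="MOSTLY_HEALTHY")
        return pd.Series(labels, index=pd.Index(patients["patient_id"],
                                                name="patient_id"), name="segment")


def classify_patient(patient: pd.Series, encounters_2012: pd.DataFrame,
                     rules: SegmentRuleSet | None = None) -> str:
    """Classify a single patient from their 2012 encounters."""
    rules = rules or SegmentRuleSet()
    one = pd.DataFrame([patient]) if isinstance(patient, (pd.Series, dict)) else patient
    return SegmentClassifier.from_rules(rules).fit().predict(one, encounters_2012).iloc[0]


def segment_cohort(patients: pd.DataFrame, encounters: pd.DataFrame,
                   rules: SegmentRuleSet | None = None) -> pd.Series:
    """Partition a cohort: Series patient_id -> segment, one label each."""
    rules = rules or SegmentRuleSet()
    return SegmentClassifier.from_rules(rules).fit().predict(patients, encounters)
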