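"""Segment labels and shared vocabulary for the six-segment framework.

The framework partitions an adult cohort, on baseline-year data alone, into
six mutually exclusive segments ordered (by convention, not by rule) from
least to most medically complex:

* ``MOSTLY_HEALTHY`` — no recognized chronic condition, no qualifying acute
  or end-of-life condition.
* ``SERIOUS_ACUTE`` — a serious acute condition (e.g. major trauma,
  emergency surgery) in the baseline year, without complex chronic disease.
* ``STABLE_CHRONIC`` — exactly the milder chronic profile: at least one but
  fewer than the "complex" number of recognized chronic conditions.
* ``COMPLEX_CHRONIC_NO_FREQ`` — multimorbid (two or more recognized chronic
  conditions) without frequent hospital admissions.
* ``COMPLEX_CHRONIC_FREQ`` — multimorbid with frequent hospital admissions
  (three or more inpatient admissions in the 12-month baseline window), a
  proxy for high-cost users.
* ``END_OF_LIFE`` — a condition with expected survival measured in months
  (e.g. metastatic cancer under palliation).
"""

from __future__ import annotations

import enum


class SegmentLabel(str, enum.Enum):
    """One of the six mutually exclusive population segments."""

    MOSTLY_HEALTHY = "MOSTLY_HEALTHY"
    SERIOUS_ACUTE = "SERIOUS_ACUTE"
    STABLE_CHRONIC = "STABLE_CHRONIC"
    COMPLEX_CHRONIC_NO_FREQ = "COMPLEX_CHRONIC_NO_FREQ"
    COMPLEX_CHRONIC_FREQ = "COMPLEX_CHRONIC_FREQ"
    END_OF_LIFE = "END_OF_LIFE"

    def __str__(self) -> str:  # keep CSV round trips clean
        return self.value


#: Canonical column/reporting order (least to most complex, as printed in
#: the framework's summary tables).
SEGMENT_ORDER: list[str] = [
    SegmentLabel.MOSTLY_HEALTHY.value,
    SegmentLabel.SERIOUS_ACUTE.value,
    SegmentLabel.STABLE_CHRONIC.value,
    SegmentLabel.COMPLEX_CHRONIC_NO_FREQ.value,
    SegmentLabel.COMPLEX_CHRONIC_FREQ.value,
    SegmentLabel.END_OF_LIFE.value,
]

#: Default classification precedence: most severe predicate wins when a
#: patient satisfies several.  Configurable via SegmentRuleSet.
DEFAULT_PRECEDENCE: list[str] = [
    SegmentLabel.END_OF_LIFE.value,
    SegmentLabel.COMPLEX_CHRONIC_FREQ.value,
    SegmentLabel.COMPLEX_CHRONIC_NO_FREQ.value,
    SegmentLabel.SERIOUS_ACUTE.value,
    SegmentLabel.STABLE_CHRONIC.value,
    SegmentLabel.MOSTLY_HEALTHY.value,
]

#: Encounter kinds: emergency department attendance, specialist outpatient
#: clinic attendance, inpatient hospital admission.
ENCOUNTER_KINDS: list[str] = ["ED", "SOC", "INPATIENT"]

#: Default chronic-condition category vocabulary shipped for simulation.
#: Stands in for a full clinical code list, which is site-specific.
DEFAULT_CHRONIC_VOCABULARY: list[str] = [
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "ischemic_heart_disease",
    "stroke",
    "copd_asthma",
    "chronic_kidney_disease",
    "heart_failure",
]

GENDERS: list[str] = ["male", "female"]
ETHNICITIES: list[str] = ["Chinese", "Malay", "Indian", "Others"]
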