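import numpy as np
import pandas as pd
import pytest

from popseg import CohortGenerator, GeneratorConfig


def make_patient(patient_id="P1", age=50, gender="female", ethnicity="Chinese",
                 death_date=None, chronic=(), serious_acute=False, eol=False):
    return {
        "patient_id": patient_id,
        "age_2012": age,
        "gender": gender,
        "ethnicity": ethnicity,
        "death_date": pd.Timestamp(death_date) if death_date else pd.NaT,
        "chronic_conditions": tuple(sorted(chronic)),
        "serious_acute": serious_acute,
        "end_of_life_condition": eol,
    }


def make_encounters(patient_id, dates, kind="INPATIENT"):
    return pd.DataFrame({
        "patient_id": patient_id,
        "date": pd.to_datetime(dates),
        "kind": kind,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """One generated cohort shared by read-only tests."""
    gen = CohortGenerator(GeneratorConfig(n_patients=2000, seed=42))
    return gen.generate()


@pytest.fixture
def archetypes():
    """Six single-patient archetypes, one per segment, plus their 2012
    encounters."""
    patients = pd.DataFrame([
        make_patient("A_MH"),
        make_patient("A_SA", serious_acute=True),
        make_patient("A_SC", chronic=("diabetes",)),
        make_patient("A_CCN", chronic=("diabetes", "hypertension")),
        make_patient("A_CCF", chronic=("diabetes", "hypertension")),
        make_patient("A_EOL", eol=True),
    ])
    enc = pd.concat([
        make_encounters("A_MH", ["2012-03-01"], "SOC"),
        make_encounters("A_SA", ["2012-04-01"], "ED"),
        make_encounters("A_SC", ["2012-05-01"], "SOC"),
        make_encounters("A_CCN", ["2012-06-01", "2012-07-01"], "INPATIENT"),
        make_encounters("A_CCF", ["2012-02-01", "2012-05-01", "2012-09-01"], "INPATIENT"),
        make_encounters("A_EOL", ["2012-08-01"], "SOC"),
    ], ignore_index=True)
    truth = {"A_MH": "MOSTLY_HEALTHY", "A_SA": "SERIOUS_ACUTE",
             "A_SC": "STABLE_CHRONIC", "A_CCN": "COMPLEX_CHRONIC_NO_FREQ",
             "A_CCF": "COMPLEX_CHRONIC_FREQ", "A_EOL": "END_OF_LIFE"}
    return patients, enc, truth


# --- independent oracles (kept deliberately naive) --------------------------

def km_brute_force(times, events):
    """Product-limit estimator computed directly over risk sets."""
    times = np.asarray(times)
    events = np.asarray(events)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def logrank_brute_force_2group(times, events, groups):
    """Two-group log-rank chi-square over pooled risk sets."""
    times = np.asarray(times)
    events = np.asarray(events)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var
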