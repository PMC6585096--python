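"""CSV persistence for patient and encounter tables.

The on-disk dialect is deliberately rigid so that round trips are lossless:

* ``patients.csv`` — patient_id, age_2012, gender, ethnicity, death_date
  (ISO-8601 ``YYYY-MM-DD`` or empty), chronic_conditions (semicolon-joined
  category ids), serious_acute (0/1), end_of_life_condition (0/1).
* ``encounters.csv`` — patient_id, date (ISO-8601), kind in {ED, SOC,
  INPATIENT}.

Any deviation (unknown kind, non-ISO date, missing column) raises
:class:`~popseg.errors.FormatError` naming the offending row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .segments import ENCOUNTER_KINDS, ETHNICITIES, GENDERS

PATIENTS_FILE = "patients.csv"
ENCOUNTERS_FILE = "encounters.csv"


def _parse_iso_dates(raw: pd.Series, column: str, allow_empty: bool) -> pd.Series:
    raw = raw.fillna("").astype(str).str.strip()
    empty = raw == ""
    if empty.any() and not allow_empty:
        row = int(np.flatnonzero(empty)[0])
        raise FormatError(f"{column}: missing date at row {row + 1}")
    parsed = pd.to_datetime(raw.where(~empty), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & ~empty
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"{column}: {raw.iloc[row]!r} at row {row + 1} is not an "
            f"ISO-8601 (YYYY-MM-DD) date")
    return parsed


def write_cohort(patients: pd.DataFrame, encounters: pd.DataFrame,
                 path: str | Path) -> None:
    """Write patients.csv and encounters.csv under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    out = patients.copy()
    out["death_date"] = pd.to_datetime(out["death_date"]).dt.strftime("%Y-%m-%d").fillna("")
    out["chronic_conditions"] = [";".join(sorted(c)) for c in out["chronic_conditions"]]
    out["serious_acute"] = out["serious_acute"].astype(int)
    out["end_of_life_condition"] = out["end_of_life_condition"].astype(int)
    out.to_csv(path / PATIENTS_FILE, index=False)

    enc = encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"]).dt.strftime("%Y-%m-%d")
    enc.to_csv(path / ENCOUNTERS_FILE, index=False)


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; strict inverse."""
    path = Path(path)
    patients = read_patients(path / PATIENTS_FILE)
    encounters = read_encounters(path / ENCOUNTERS_FILE)
    return patients, encounters


def read_patients(file: str | Path) -> pd.DataFrame:
    df = pd.read_csv(file, dtype={"patient_id": str}, keep_default_na=False)
    required = {"patient_id", "age_2012", "gender", "ethnicity", "death_date",
                "chronic_conditions", "serious_acute", "end_of_life_condition"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{file}: missing columns {sorted(missing)}")
    df["death_date"] = _parse_iso_dates(df["death_date"], "death_date", allow_empty=True)
    for col, allowed in (("gender", GENDERS), ("ethnicity", ETHNICITIES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{col}: {df[col].iloc[row]!r} at row {row + 1} not in {allowed}")
    df["age_2012"] = pd.to_numeric(df["age_2012"], errors="raise").astype(np.int64)
    df["chronic_conditions"] = [
        tuple(sorted(c.split(";"))) if c else () for c in df["chronic_conditions"].astype(str)
    ]
    df["serious_acute"] = df["serious_acute"].astype(int).astype(bool)
    df["end_of_life_condition"] = df["end_of_life_condition"].astype(int).astype(bool)
    return df


def read_encounters(file: str | Path) -> pd.DataFrame:
    df = pd.read_csv(file, dtype={"patient_id": str}, keep_default_na=False)
    missing = {"patient_id", "date", "kind"} - set(df.columns)
    if missing:
        raise FormatError(f"{file}: missing columns {sorted(missing)}")
    bad = ~df["kind"].isin(ENCOUNTER_KINDS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"kind: {df['kind'].iloc[row]!r} at row {row + 1} not in {ENCOUNTER_KINDS}")
    df["date"] = _parse_iso_dates(df["date"], "date", allow_empty=False)
    return df
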