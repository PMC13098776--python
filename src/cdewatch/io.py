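"""CSV interchange: readers, writers and table validation.

All tables are UTF-8 CSV with ISO-8601 timezone-naive timestamps.
Schemas:

* ``admissions.csv`` — patient_id, admission_id, encounter_id,
  encounter_start, picu_start, picu_end, age_years, sex, race,
  ethnicity, insurance
* ``events.csv`` — admission_id, event_type, event_time, extubation_time
  (empty allowed)
* ``observations.csv`` — admission_id, obs_time, variable, value, category
* ``scores.csv`` / ``indicator.csv`` — admission_id, time, probability
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import ADMISSION_COLUMNS, RAW_EVENT_TYPES, CDE_TYPES

EVENT_COLUMNS = ["admission_id", "event_type", "event_time",
                 "extubation_time"]
OBSERVATION_COLUMNS = ["admission_id", "obs_time", "variable", "value",
                       "category"]
SCORE_COLUMNS = ["admission_id", "time", "probability"]
OBSERVATION_CATEGORIES = {"medication", "laboratory", "vital"}


class TableValidationError(ValueError):
    """A CSV violates its schema or referential integrity."""


def _read(path, date_columns, required):
    df = pd.read_csv(path, dtype={"admission_id": str, "patient_id": str,
                                  "encounter_id": str})
    missing = set(required) - set(df.columns)
    if missing:
        raise TableValidationError(
            f"{path}: missing columns {sorted(missing)}")
    for col in date_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def read_admissions(path) -> pd.DataFrame:
    return _read(path, ["encounter_start", "picu_start", "picu_end"],
                 ADMISSION_COLUMNS)


def read_events(path) -> pd.DataFrame:
    return _read(path, ["event_time", "extubation_time"],
                 [c for c in EVENT_COLUMNS if c != "extubation_time"])


def read_observations(path) -> pd.DataFrame:
    return _read(path, ["obs_time"], OBSERVATION_COLUMNS)


def read_scores(path) -> pd.DataFrame:
    return _read(path, ["time"], SCORE_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str))


def validate_tables(admissions_path=None, events_path=None,
                    observations_path=None) -> list[str]:
    """Schema, parseability, domain and referential-integrity checks.

    Returns a list of human-readable issues (empty = clean); reading
    errors become issues rather than exceptions so one broken file does
    not mask the rest.
    """
    issues: list[str] = []
    adm = ev = obs = None

    if admissions_path is not None:
        try:
            adm = read_admissions(admissions_path)
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            issues.append(f"admissions: {exc}")
        if adm is not None:
            bad = adm["picu_end"] <= adm["picu_start"]
            for i in adm.index[bad]:
                issues.append(f"admissions row {i}: picu_end <= picu_start")
            bad_age = (adm["age_years"].astype(float) < 0)
            for i in adm.index[bad_age]:
                issues.append(f"admissions row {i}: negative age")
            dup = adm["admission_id"].duplicated()
            for i in adm.index[dup]:
                issues.append(f"admissions row {i}: duplicate admission_id")

    def _check_refs(df, label):
        if adm is None:
            return
        known = set(adm["admission_id"])
        bad = ~df["admission_id"].isin(known)
        for i in df.index[bad]:
            issues.append(f"{label} row {i}: unknown admission_id "
                          f"{df.at[i, 'admission_id']!r}")

    def _check_bounds(df, time_col, label):
        if adm is None:
            return
        bounds = adm.set_index("admission_id")[["picu_start", "picu_end"]]
        sel = df["admission_id"].isin(bounds.index)
        sub = df[sel]
        start = bounds["picu_start"].reindex(sub["admission_id"]).to_numpy()
        end = bounds["picu_end"].reindex(sub["admission_id"]).to_numpy()
        t = sub[time_col].to_numpy()
        bad = (t < start) | (t > end)
        for i in sub.index[bad]:
            issues.append(
                f"{label} row {i}: {time_col} outside the PICU stay")

    if events_path is not None:
        try:
            ev = read_events(events_path)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"events: {exc}")
        if ev is not None:
            allowed = RAW_EVENT_TYPES | CDE_TYPES
            bad = ~ev["event_type"].isin(allowed)
            for i in ev.index[bad]:
                issues.append(f"events row {i}: unknown event_type "
                              f"{ev.at[i, 'event_type']!r}")
            _check_refs(ev, "events")
            _check_bounds(ev, "event_time", "events")

    if observations_path is not None:
        try:
            obs = read_observations(observations_path)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"observations: {exc}")
        if obs is not None:
            bad = ~obs["category"].isin(OBSERVATION_CATEGORIES)
            for i in obs.index[bad]:
                issues.append(f"observations row {i}: unknown category "
                              f"{obs.at[i, 'category']!r}")
            nonfinite = ~pd.to_numeric(obs["value"],
                                       errors="coerce").notna()
            for i in obs.index[nonfinite]:
                issues.append(f"observations row {i}: non-numeric value")
            _check_refs(obs, "observations")
            _check_bounds(obs, "obs_time", "observations")

    return issues
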