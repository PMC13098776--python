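"""Cohort and critical-deterioration-event (CDE) construction.

Turns raw PICU stay records and raw clinical events into the analyzable
cohort: stays in the same hospital encounter separated by less than 24 h
are merged, admissions shorter than 24 h or older than 24 y are excluded,
intubations are confirmed as unplanned endotracheal intubations (UEI) by
the 48-h persistence rule, confirmed events are deduplicated with an 8-h
lockout, the cohort is split temporally, and horizon-labelled training
samples are drawn.

All timestamps are timezone-naive at minute resolution; durations are
computed in minutes and reported in hours.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: PICU-absence gap below which two stays in one encounter are one admission.
MERGE_GAP_HOURS = 24.0
#: Minimum stay duration for cohort inclusion.
MIN_STAY_HOURS = 24.0
#: Upper age bound (exclusive): "0-24 years old" read as age < 25.
MAX_AGE_YEARS = 25.0
#: Intubation persistence required to confirm an unplanned intubation.
UEI_PERSIST_HOURS = 48.0
#: Lockout after a kept CDE within which later CDEs are the same trajectory.
DEDUP_LOCKOUT_HOURS = 8.0
#: Training exclusions: first hours of the stay and final hours before discharge.
EARLY_EXCLUDE_HOURS = 16.0
LATE_EXCLUDE_HOURS = 6.0
#: Prediction horizons (hours before the event) of the ensemble members.
HORIZONS = (1, 2, 4, 6, 8, 12)

#: Raw event vocabulary; INTUBATION becomes UEI once the 48-h rule confirms it.
RAW_EVENT_TYPES = frozenset({"CPR", "ECMO", "EPI_BOLUS", "INTUBATION"})
CDE_TYPES = frozenset({"CPR", "ECMO", "EPI_BOLUS", "UEI"})

ADMISSION_COLUMNS = [
    "patient_id", "admission_id", "encounter_id", "encounter_start",
    "picu_start", "picu_end", "age_years", "sex", "race", "ethnicity",
    "insurance",
]


class CohortValidationError(ValueError):
    """Raised when input tables violate the cohort contracts."""


@dataclass(frozen=True)
class CohortSplit:
    """Temporal partition of admissions around a boundary date.

    ``excluded`` holds straddlers: admissions whose PICU stay starts on or
    after the boundary but whose hospital encounter began before it.  They
    belong to neither period and are dropped from modelling.
    """

    development: frozenset
    validation: frozenset
    excluded: frozenset
    boundary_date: pd.Timestamp

    def assignment(self, admission_id) -> str:
        if admission_id in self.development:
            return "development"
        if admission_id in self.validation:
            return "validation"
        if admission_id in self.excluded:
            return "excluded"
        raise KeyError(admission_id)


def admission_rng(seed: int, admission_id, purpose: str) -> np.random.Generator:
    """Per-admission random stream derived by hashing (admission_id, purpose).

    Editing unrelated admissions never reshuffles another admission's draws.
    """
    digest = hashlib.sha256(
        f"{seed}:{admission_id}:{purpose}".encode()
    ).digest()
    return np.random.default_rng(np.frombuffer(digest[:16], dtype=np.uint64))


def _hours(delta) -> float:
    return pd.Timedelta(delta).total_seconds() / 3600.0


def merge_admissions(admissions: pd.DataFrame,
                     max_gap_hours: float = MERGE_GAP_HOURS) -> pd.DataFrame:
    """Combine PICU stays within one hospital encounter separated by < 24 h.

    Stays in the same encounter whose PICU-absence gap is shorter than
    ``max_gap_hours`` become one continuous admission spanning the earliest
    start to the latest end; gaps of 24 h or more remain separate
    admissions.  Overlapping stays within an encounter are rejected.

    The merged row keeps the identifier and demographics of the earliest
    stay.  Idempotent: merging an already-merged table is a no-op.
    """
    if admissions.empty:
        return admissions.copy()
    adm = admissions.copy()
    adm["picu_start"] = pd.to_datetime(adm["picu_start"])
    adm["picu_end"] = pd.to_datetime(adm["picu_end"])
    if (adm["picu_end"] <= adm["picu_start"]).any():
        bad = adm.loc[adm["picu_end"] <= adm["picu_start"], "admission_id"]
        raise CohortValidationError(
            f"picu_end <= picu_start for admission(s) {list(bad)}")

    merged_rows = []
    for _, grp in adm.groupby("encounter_id", sort=False):
        grp = grp.sort_values("picu_start")
        starts = grp["picu_start"].to_numpy()
        ends = grp["picu_end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise CohortValidationError(
                f"overlapping stays within encounter "
                f"{grp['encounter_id'].iloc[0]!r}")
        current = grp.iloc[0].copy()
        for _, stay in grp.iloc[1:].iterrows():
            gap_h = _hours(stay["picu_start"] - current["picu_end"])
            if gap_h < max_gap_hours:
                current["picu_end"] = stay["picu_end"]
            else:
                merged_rows.append(current)
                current = stay.copy()
        merged_rows.append(current)
    out = pd.DataFrame(merged_rows).reset_index(drop=True)
    return out[adm.columns]


def apply_inclusion(admissions: pd.DataFrame,
                    min_stay_hours: float = MIN_STAY_HOURS,
                    max_age_years: float = MAX_AGE_YEARS
                    ) -> tuple[pd.DataFrame, dict]:
    """Retain admissions with duration >= 24 h and age in [0, 25) years.

    Returns the filtered table and a flowchart-style count record
    (input, excluded by duration, excluded by age among the remainder,
    retained).
    """
    adm = admissions.copy()
    duration_h = (pd.to_datetime(adm["picu_end"])
                  - pd.to_datetime(adm["picu_start"])).dt.total_seconds() / 3600.0
    dur_ok = duration_h >= min_stay_hours
    age = adm["age_years"].astype(float)
    age_ok = (age >= 0.0) & (age < max_age_years)
    retained = adm[dur_ok & age_ok].reset_index(drop=True)
    flow = {
        "n_input": int(len(adm)),
        "n_excluded_duration": int((~dur_ok).sum()),
        "n_excluded_age": int((dur_ok & ~age_ok).sum()),
        "n_retained": int(len(retained)),
    }
    return retained, flow


def classify_uei(event_time, extubation_time, admission_end,
                 persist_hours: float = UEI_PERSIST_HOURS) -> bool:
    """Confirm an intubation as an unplanned endotracheal intubation.

    Confirmed iff the intubation persisted >= 48 h.  An intubation still
    ongoing at the end of the admission (missing extubation time) is
    confirmed regardless of elapsed time: discharge or death censors
    persistence, and deterioration is presumed.
    """
    event_time = pd.Timestamp(event_time)
    if extubation_time is None or pd.isna(extubation_time):
        return True
    extubation_time = pd.Timestamp(extubation_time)
    if extubation_time < event_time:
        raise CohortValidationError(
            f"extubation at {extubation_time} precedes intubation "
            f"at {event_time}")
    return _hours(extubation_time - event_time) >= persist_hours


def confirm_events(events: pd.DataFrame, admissions: pd.DataFrame,
                   persist_hours: float = UEI_PERSIST_HOURS) -> pd.DataFrame:
    """Map raw events to confirmed CDE candidates.

    CPR / ECMO / EPI_BOLUS rows pass through; INTUBATION rows are confirmed
    as UEI by :func:`classify_uei` (rows carrying a truthy ``planned``
    column are dropped before the rule).  Events outside their admission's
    stay are rejected.  Output columns: admission_id, event_type,
    event_time, ongoing_at_end (flag for sensitivity analysis).
    """
    if events.empty:
        return pd.DataFrame(
            columns=["admission_id", "event_type", "event_time",
                     "ongoing_at_end"])
    ev = events.copy()
    ev["event_time"] = pd.to_datetime(ev["event_time"])
    if "extubation_time" in ev.columns:
        ev["extubation_time"] = pd.to_datetime(ev["extubation_time"])
    else:
        ev["extubation_time"] = pd.NaT
    unknown = set(ev["event_type"]) - RAW_EVENT_TYPES - CDE_TYPES
    if unknown:
        raise CohortValidationError(f"unknown event types: {sorted(unknown)}")

    bounds = admissions.set_index("admission_id")[["picu_start", "picu_end"]]
    missing = set(ev["admission_id"]) - set(bounds.index)
    if missing:
        raise CohortValidationError(
            f"events reference unknown admissions: {sorted(map(str, missing))[:5]}")
    start = bounds["picu_start"].reindex(ev["admission_id"]).to_numpy()
    end = bounds["picu_end"].reindex(ev["admission_id"]).to_numpy()
    t = ev["event_time"].to_numpy()
    outside = (t < start) | (t > end)
    if outside.any():
        row = ev.index[outside][0]
        raise CohortValidationError(
            f"event at row {row} outside its admission's PICU stay")

    if "planned" in ev.columns:
        ev = ev[~ev["planned"].fillna(False).astype(bool)]

    rows = []
    end_by_adm = bounds["picu_end"]
    for _, r in ev.iterrows():
        etype = r["event_type"]
        ongoing = False
        if etype == "INTUBATION":
            ongoing = pd.isna(r["extubation_time"])
            if not classify_uei(r["event_time"], r["extubation_time"],
                                end_by_adm[r["admission_id"]], persist_hours):
                continue
            etype = "UEI"
        rows.append({"admission_id": r["admission_id"], "event_type": etype,
                     "event_time": r["event_time"], "ongoing_at_end": ongoing})
    out = pd.DataFrame(rows, columns=["admission_id", "event_type",
                                      "event_time", "ongoing_at_end"])
    return out.sort_values(["admission_id", "event_time"],
                           kind="stable").reset_index(drop=True)


def deduplicate_events(events: pd.DataFrame,
                       lockout_hours: float = DEDUP_LOCKOUT_HOURS,
                       anchor_on_kept: bool = True) -> pd.DataFrame:
    """Suppress CDEs within 8 h of a prior event in the same admission.

    Chronological greedy pass: the first event is always kept; a later
    event is kept iff it is at least ``lockout_hours`` after the anchor.
    With ``anchor_on_kept`` (default) the anchor is the last *kept* event
    (e.g., events at t, t+5, t+9 keep t and t+9); with the alternative
    convention the anchor re-sets on every raw event, so a run of closely
    spaced events suppresses everything after its first member.
    """
    if events.empty:
        return events.copy()
    ev = events.copy()
    ev["event_time"] = pd.to_datetime(ev["event_time"])
    kept_idx = []
    for _, grp in ev.groupby("admission_id", sort=False):
        grp = grp.sort_values("event_time", kind="stable")
        anchor = None
        for idx, r in grp.iterrows():
            t = r["event_time"]
            if anchor is None or _hours(t - anchor) >= lockout_hours:
                kept_idx.append(idx)
                anchor = t
            elif not anchor_on_kept:
                anchor = t
    return ev.loc[kept_idx].sort_values(
        ["admission_id", "event_time"], kind="stable").reset_index(drop=True)


def temporal_split(admissions: pd.DataFrame, boundary_date) -> CohortSplit:
    """Partition admissions into development / validation / excluded sets.

    Development: PICU start before the boundary.  Validation: both the
    PICU start and the hospital encounter start on or after the boundary.
    Straddlers (PICU start after the boundary, encounter begun before it)
    are excluded from both periods.
    """
    boundary = pd.Timestamp(boundary_date)
    picu_start = pd.to_datetime(admissions["picu_start"])
    enc_start = pd.to_datetime(admissions["encounter_start"])
    dev = picu_start < boundary
    val = (picu_start >= boundary) & (enc_start >= boundary)
    ids = admissions["admission_id"]
    return CohortSplit(
        development=frozenset(ids[dev]),
        validation=frozenset(ids[val]),
        excluded=frozenset(ids[~dev & ~val]),
        boundary_date=boundary,
    )


def build_training_samples(admissions: pd.DataFrame, events: pd.DataFrame,
                           horizons=HORIZONS, seed: int = 0,
                           early_exclude_hours: float = EARLY_EXCLUDE_HOURS,
                           late_exclude_hours: float = LATE_EXCLUDE_HOURS
                           ) -> pd.DataFrame:
    """Draw horizon-labelled positive snapshots and one control per admission.

    Events within the first 16 h of their admission never become training
    targets; an admission whose only CDEs are that early contributes
    nothing.  Each remaining CDE yields one positive sample per horizon at
    ``event_time - h`` (dropped if before the PICU start).  Each non-CDE
    admission contributes a single control time drawn uniformly at
    1-minute resolution from the closed window
    [picu_start + 16 h, picu_end - 6 h], shared across horizons.

    Returns columns: admission_id, snapshot_time, horizon (NA for
    controls), label.  Reproducible given ``seed``; per-admission draws
    are independent streams.
    """
    adm = admissions.copy()
    adm["picu_start"] = pd.to_datetime(adm["picu_start"])
    adm["picu_end"] = pd.to_datetime(adm["picu_end"])
    ev = events.copy()
    if not ev.empty:
        ev["event_time"] = pd.to_datetime(ev["event_time"])
    start_by_adm = adm.set_index("admission_id")["picu_start"]
    end_by_adm = adm.set_index("admission_id")["picu_end"]

    rows = []
    event_admissions = set(ev["admission_id"]) if not ev.empty else set()
    for aid, grp in (ev.groupby("admission_id", sort=False)
                     if not ev.empty else ()):
        start = start_by_adm[aid]
        late_enough = grp["event_time"] - start >= pd.Timedelta(
            hours=early_exclude_hours)
        for t in grp.loc[late_enough, "event_time"]:
            for h in horizons:
                snap = t - pd.Timedelta(hours=h)
                if snap >= start:
                    rows.append({"admission_id": aid, "snapshot_time": snap,
                                 "horizon": h, "label": 1})

    for _, r in adm.iterrows():
        aid = r["admission_id"]
        if aid in event_admissions:
            continue
        lo = r["picu_start"] + pd.Timedelta(hours=early_exclude_hours)
        hi = r["picu_end"] - pd.Timedelta(hours=late_exclude_hours)
        n_minutes = int(_hours(hi - lo) * 60)
        if n_minutes < 0:
            import warnings
            warnings.warn(
                f"admission {aid!r} has no eligible control window; skipped")
            continue
        rng = admission_rng(seed, aid, "control-time")
        snap = lo + pd.Timedelta(minutes=int(rng.integers(0, n_minutes + 1)))
        rows.append({"admission_id": aid, "snapshot_time": snap,
                     "horizon": pd.NA, "label": 0})

    out = pd.DataFrame(rows, columns=["admission_id", "snapshot_time",
                                      "horizon", "label"])
    out["horizon"] = out["horizon"].astype("Int64")
    out["label"] = out["label"].astype(int)
    return out.sort_values(["admission_id", "snapshot_time", "horizon"],
                           kind="stable", na_position="first"
                           ).reset_index(drop=True)
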