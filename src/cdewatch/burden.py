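"""Deployment-emulating alert-burden analysis.

Replays a risk score (or a binary comparator tool) over each admission as
a prospective alerting system would consume it: probabilities are read on
a fixed prediction grid, an alert fires when the probability reaches the
threshold, each alert opens a refractory period during which no further
alerts fire, and a censoring period after every deterioration event
suppresses alerts that carry no preparatory value.

The resulting metrics quantify the detection-versus-burden tradeoff:
alerts per patient-day, the fraction of events with an alert in the
24 hours before them, alert-to-event lead times, and the admission-level
number needed to alert (NNA).

Conventions (each documented and tested):
  * threshold comparison is ``>=`` (so a binary stream at threshold 0.5
    behaves like strict-exceed at any cut below 1); ``strict`` switches
    to ``>``;
  * the refractory period blocks the open interval ``(a, a + R)`` — the
    first grid point at or after ``a + R`` is eligible;
  * the censor interval is ``[e, e + C)`` — alerts resume exactly C hours
    after the event;
  * the detection window is half-open ``[e - W, e)`` — an alert at the
    event instant is not advance warning;
  * lead time uses the earliest qualifying alert in the window
    (maximal preparation time); ``lead_convention="latest"`` flips this;
  * the patient-day denominator is the full stay, censored and refractory
    time included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AlertPolicy:
    """Deployment parameters of the emulated alerting system."""

    interval_hours: float = 1.0
    threshold: float = 0.5
    refractory_hours: float = 12.0
    censor_hours: float = 24.0
    window_hours: float = 24.0
    strict: bool = False
    lead_convention: str = "earliest"  # or "latest"

    def __post_init__(self):
        if self.interval_hours <= 0:
            raise ValueError("prediction interval must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if min(self.refractory_hours, self.censor_hours,
               self.window_hours) < 0:
            raise ValueError("refractory/censor/window must be non-negative")
        if self.lead_convention not in ("earliest", "latest"):
            raise ValueError("lead_convention must be 'earliest' or 'latest'")


@dataclass(frozen=True)
class BurdenReport:
    """Burden / detection / lead-time metrics for one policy + threshold."""

    threshold: float
    alerts_per_patient_day: float
    detection_fraction: float  # NaN when there are no events
    lead_median_hours: float
    lead_iqr_hours: tuple[float, float]
    admission_nna: float  # NaN when no flagged admission has a detection
    n_alerts: int
    n_events: int
    n_detected: int
    n_flagged_admissions: int
    patient_days: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        lo, hi = d.pop("lead_iqr_hours")
        d["lead_iqr_lo_hours"], d["lead_iqr_hi_hours"] = lo, hi
        return d


def prediction_grid(picu_start, picu_end, interval_hours: float
                    ) -> pd.DatetimeIndex:
    """Grid of prediction times: start, start + Δ, ... up to and including end."""
    if interval_hours <= 0:
        raise ValueError("prediction interval must be positive")
    return pd.date_range(pd.Timestamp(picu_start), pd.Timestamp(picu_end),
                         freq=pd.Timedelta(hours=interval_hours))


def simulate_alerts_hours(grid_h: np.ndarray, probs: np.ndarray,
                          events_h: np.ndarray, policy: AlertPolicy
                          ) -> np.ndarray:
    """Chronological alert scan on a single admission, times in hours.

    Fires at grid time t iff the probability reaches the threshold, t is
    not inside the refractory window opened by the previous alert, and t
    is not inside any event's censor window.  The refractory re-anchors
    on each fired alert.  Deterministic.
    """
    grid_h = np.asarray(grid_h, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if len(grid_h) != len(probs):
        raise ValueError("grid and probabilities must align")
    if len(grid_h) > 1 and (np.diff(grid_h) <= 0).any():
        raise ValueError("prediction grid must be strictly increasing")
    events_h = np.sort(np.asarray(events_h, dtype=float))
    hot = probs > policy.threshold if policy.strict else \
        probs >= policy.threshold
    alerts = []
    last = -np.inf
    R, C = policy.refractory_hours, policy.censor_hours
    for t, fire in zip(grid_h, hot):
        if not fire:
            continue
        if t < last + R:  # open interval (last, last + R); t > last on a grid
            continue
        j = np.searchsorted(events_h, t, side="right") - 1
        if j >= 0 and t < events_h[j] + C:  # censor [e, e + C)
            continue
        alerts.append(t)
        last = t
    return np.asarray(alerts, dtype=float)


def _to_hours(times, origin) -> np.ndarray:
    s = pd.to_datetime(pd.Series(times))
    return ((s - pd.Timestamp(origin)).dt.total_seconds() / 3600.0).to_numpy()


def simulate_alerts(scores: pd.DataFrame, events: pd.DataFrame,
                    admissions: pd.DataFrame, policy: AlertPolicy
                    ) -> pd.DataFrame:
    """Alert stream for every admission in a cohort.

    ``scores`` has columns admission_id, time, probability on each
    admission's prediction grid; ``events`` holds all confirmed events
    (including those in the first 16 h — no training-style exclusions
    here).  Returns admission_id, alert_time, probability rows.
    """
    adm = admissions.set_index("admission_id")
    ev_by_adm = (dict(list(events.groupby("admission_id", sort=False)))
                 if not events.empty else {})
    rows = []
    for aid, grp in scores.groupby("admission_id", sort=False):
        start = pd.Timestamp(adm.loc[aid, "picu_start"])
        grp = grp.sort_values("time", kind="stable")
        grid_h = _to_hours(grp["time"], start)
        probs = grp["probability"].to_numpy(dtype=float)
        ev = ev_by_adm.get(aid)
        events_h = (_to_hours(ev["event_time"], start)
                    if ev is not None else np.empty(0))
        alert_h = simulate_alerts_hours(grid_h, probs, events_h, policy)
        lut = dict(zip(grid_h, probs))
        for t in alert_h:
            rows.append({"admission_id": aid,
                         "alert_time": start + pd.Timedelta(hours=t),
                         "probability": lut[t]})
    return pd.DataFrame(rows, columns=["admission_id", "alert_time",
                                       "probability"])


def detection_flags_hours(alert_h: np.ndarray, events_h: np.ndarray,
                          window_hours: float) -> np.ndarray:
    """Per-event detected flag: any alert in [e - W, e), single admission."""
    alert_h = np.sort(np.asarray(alert_h, dtype=float))
    events_h = np.asarray(events_h, dtype=float)
    lo = np.searchsorted(alert_h, events_h - window_hours, side="left")
    hi = np.searchsorted(alert_h, events_h, side="left")
    return hi > lo


def detection_fraction(alerts: pd.DataFrame, events: pd.DataFrame,
                       window_hours: float = 24.0
                       ) -> tuple[float, pd.DataFrame]:
    """Fraction of events with an alert in the preceding window, plus flags.

    Returns NaN (not-applicable) when there are no events.
    """
    ev = events.copy()
    if ev.empty:
        ev["detected"] = pd.Series(dtype=bool)
        return float("nan"), ev
    ev["event_time"] = pd.to_datetime(ev["event_time"])
    al_by_adm = (dict(list(alerts.groupby("admission_id", sort=False)))
                 if not alerts.empty else {})
    flags = np.zeros(len(ev), dtype=bool)
    for aid, idx in ev.groupby("admission_id", sort=False).indices.items():
        al = al_by_adm.get(aid)
        if al is None:
            continue
        origin = ev["event_time"].iloc[idx[0]]
        flags[idx] = detection_flags_hours(
            _to_hours(al["alert_time"], origin),
            _to_hours(ev["event_time"].iloc[idx], origin), window_hours)
    ev["detected"] = flags
    return float(flags.mean()), ev


def _lead_times_hours(alerts: pd.DataFrame, events: pd.DataFrame,
                      window_hours: float, convention: str) -> np.ndarray:
    """Lead time per detected event from its earliest (or latest) window alert."""
    leads = []
    al_by_adm = (dict(list(alerts.groupby("admission_id", sort=False)))
                 if not alerts.empty else {})
    for aid, grp in events.groupby("admission_id", sort=False):
        al = al_by_adm.get(aid)
        if al is None:
            continue
        for e in pd.to_datetime(grp["event_time"]):
            a_h = _to_hours(al["alert_time"], e)
            qualifying = a_h[(a_h >= -window_hours) & (a_h < 0)]
            if len(qualifying):
                best = qualifying.min() if convention == "earliest" \
                    else qualifying.max()
                leads.append(-best)
    return np.asarray(leads, dtype=float)


def burden_metrics(alerts: pd.DataFrame, events: pd.DataFrame,
                   admissions: pd.DataFrame, policy: AlertPolicy
                   ) -> BurdenReport:
    """Aggregate alert burden, detection and lead-time metrics.

    Patient-days are summed full-stay durations / 24 h (censored and
    refractory periods included in the denominator).  Admission-level
    NNA = flagged admissions per flagged admission with a detected event.
    """
    durations_h = (pd.to_datetime(admissions["picu_end"])
                   - pd.to_datetime(admissions["picu_start"])
                   ).dt.total_seconds() / 3600.0
    patient_days = float(durations_h.sum() / 24.0)
    if patient_days <= 0:
        raise ValueError("zero patient-days in the cohort")

    frac, flagged_events = detection_fraction(alerts, events,
                                              policy.window_hours)
    leads = _lead_times_hours(alerts, events, policy.window_hours,
                              policy.lead_convention)
    lead_median = float(np.median(leads)) if len(leads) else float("nan")
    lead_iqr = (tuple(np.percentile(leads, [25, 75])) if len(leads)
                else (float("nan"), float("nan")))

    flagged_adm = set(alerts["admission_id"]) if not alerts.empty else set()
    detected_adm = (set(flagged_events.loc[flagged_events["detected"],
                                           "admission_id"])
                    if not flagged_events.empty else set())
    n_flagged = len(flagged_adm)
    n_flagged_detected = len(flagged_adm & detected_adm)
    nna = (n_flagged / n_flagged_detected if n_flagged_detected
           else float("nan"))

    return BurdenReport(
        threshold=policy.threshold,
        alerts_per_patient_day=len(alerts) / patient_days,
        detection_fraction=frac,
        lead_median_hours=lead_median,
        lead_iqr_hours=(float(lead_iqr[0]), float(lead_iqr[1])),
        admission_nna=nna,
        n_alerts=int(len(alerts)),
        n_events=int(len(events)),
        n_detected=int(flagged_events["detected"].sum())
        if not flagged_events.empty else 0,
        n_flagged_admissions=n_flagged,
        patient_days=patient_days,
    )


@dataclass(frozen=True)
class SweepCurve:
    """Burden reports across an ascending threshold grid."""

    thresholds: tuple
    reports: tuple

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])


def sweep_thresholds(scores: pd.DataFrame, events: pd.DataFrame,
                     admissions: pd.DataFrame, policy: AlertPolicy,
                     thresholds) -> SweepCurve:
    """One burden report per threshold; monotonicity post-checked.

    Detection fraction and alerts per patient-day should be non-increasing
    in the threshold; a violation (possible only through refractory
    interactions) is surfaced as a warning, not silently repaired.
    """
    thresholds = sorted(float(t) for t in thresholds)
    reports = []
    for thr in thresholds:
        pol = replace(policy, threshold=thr)
        alerts = simulate_alerts(scores, events, admissions, pol)
        reports.append(burden_metrics(alerts, events, admissions, pol))
    for prev, cur in zip(reports, reports[1:]):
        if cur.alerts_per_patient_day > prev.alerts_per_patient_day + 1e-12:
            warnings.warn("alert burden increased with threshold "
                          f"({prev.threshold} -> {cur.threshold})")
        if (np.isfinite(cur.detection_fraction)
                and np.isfinite(prev.detection_fraction)
                and cur.detection_fraction > prev.detection_fraction + 1e-12):
            warnings.warn("detection fraction increased with threshold "
                          f"({prev.threshold} -> {cur.threshold})")
    return SweepCurve(thresholds=tuple(thresholds), reports=tuple(reports))


class UnreachableDetectionError(ValueError):
    """The sweep never reaches the requested detection fraction."""


def threshold_for_detection(curve: SweepCurve, target: float
                            ) -> tuple[float, BurdenReport]:
    """Largest threshold whose detection fraction meets the target.

    The largest qualifying threshold carries the minimal alert burden at
    the required detection level.
    """
    if not curve.reports:
        raise ValueError("empty sweep curve")
    best = None
    for thr, rep in zip(curve.thresholds, curve.reports):
        frac = rep.detection_fraction
        if np.isfinite(frac) and frac >= target:
            best = (thr, rep)
    if best is None:
        raise UnreachableDetectionError(
            f"no threshold reaches detection fraction {target}")
    return best


def binary_tool_burden(indicator: pd.DataFrame, events: pd.DataFrame,
                       admissions: pd.DataFrame, policy: AlertPolicy
                       ) -> BurdenReport:
    """Burden metrics for a binary comparator tool's hourly indicator stream.

    The 0/1 indicator is treated as a probability with threshold 0.5 and
    pushed through the same simulator, refractory and censoring as any
    risk score.
    """
    values = indicator["probability"].to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("binary tool stream must contain only 0/1 values")
    pol = replace(policy, threshold=0.5)
    alerts = simulate_alerts(indicator, events, admissions, pol)
    return burden_metrics(alerts, events, admissions, pol)
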