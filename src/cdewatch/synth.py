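"""Synthetic PICU EHR-timeline generator.

Emits admissions, irregular long-format observation streams and raw
clinical events with a controllable pre-event deterioration signature so
the whole pipeline is testable without any real data.  The generator
emulates the structure of a single-center PICU cohort: roughly 4-6% of
admissions experience a critical deterioration event, vitals arrive on
average hourly and labs every eight hours with exponential gaps, and a
linear physiologic drift of configurable lead time and standardized
magnitude precedes each event.

Vitals and labs follow baseline + patient effect + continuous-time AR(1)
noise; medications are Poisson administration streams whose rate is
multiplied in the pre-event window.  Intubation events carry extubation
times that straddle the 48-hour persistence rule so the unplanned-
intubation classifier is exercised in both directions.

Also provides closed-form oracles for the alert simulator: Bernoulli
exceedance scores and the renewal-theory expected alert rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import admission_rng
from .burden import prediction_grid

#: Event-type mix of a development-scale PICU cohort (CPR / ECMO / dilute-
#: epinephrine bolus / intubation candidates), as observed fractions.
DEFAULT_EVENT_MIX = {
    "CPR": 177 / 1245,
    "ECMO": 17 / 1245,
    "EPI_BOLUS": 413 / 1245,
    "INTUBATION": 638 / 1245,
}

#: (baseline, within-patient scale, drift sign) per vital / lab.  Signs
#: encode the direction of deterioration (tachycardia, desaturation,
#: hypotension, rising lactate ...).
DEFAULT_VITALS = {
    "HR": (120.0, 15.0, +1.0),
    "RR": (30.0, 6.0, +1.0),
    "SBP": (95.0, 12.0, -1.0),
    "DBP": (55.0, 8.0, -1.0),
    "SPO2": (97.0, 2.0, -1.0),
}
DEFAULT_LABS = {
    "LACTATE": (1.5, 0.8, +1.0),
    "CREATININE": (0.5, 0.2, +1.0),
    "WBC": (9.0, 3.0, +1.0),
    "PLATELETS": (250.0, 60.0, -1.0),
}
#: Base administration rates per hour.
DEFAULT_MEDICATIONS = {
    "MORPHINE": 0.04,
    "FUROSEMIDE": 0.03,
    "EPINEPHRINE_INFUSION": 0.01,
}

#: Demographic category marginals of a representative PICU population
#: (female fraction, race / ethnicity / insurance mixes); independent of
#: events by construction so fairness analyses have a true null.
DEMOGRAPHIC_MARGINALS = {
    "sex": (["F", "M"], [0.56, 0.44]),
    "race": (["White", "Black", "Other", "Unknown", "Conflict"],
             [0.49, 0.28, 0.20, 0.01, 0.02]),
    "ethnicity": (["Hispanic", "Non-Hispanic", "Unknown"],
                  [0.13, 0.86, 0.01]),
    "insurance": (["Private", "Medicaid", "Medicare", "Charity",
                   "Selfpay/other", "Unknown"],
                  [0.50, 0.41, 0.004, 0.002, 0.026, 0.058]),
}
#: Age-category mix: (lo years, hi years, probability).
AGE_CATEGORIES = [
    (0.0, 28 / 365.25, 0.01),    # neonate
    (28 / 365.25, 2.0, 0.39),    # infant
    (2.0, 12.0, 0.37),           # child
    (12.0, 19.0, 0.21),          # adolescent
    (19.0, 25.0, 0.02),          # young adult
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 500
    readmission_prob: float = 0.10
    same_encounter_prob: float = 0.5   # readmission inside the same encounter
    stay_median_hours: float = 72.0    # log-normal stay lengths
    stay_sigma_log: float = 0.5
    min_stay_hours: float = 24.0
    emit_short_stays: bool = False     # add sub-24-h stays for the filter
    short_stay_prob: float = 0.05
    event_prob: float = 0.05           # admission-level event probability
    second_event_prob: float = 0.15
    #: earliest event time (hours into the stay).  Set to the training
    #: early-exclusion (16 h) plus the longest horizon (12 h) so every
    #: horizon snapshot of an event shares the controls' support
    #: ([16 h, end)); otherwise position-in-stay, not physiology, would
    #: separate the classes even with a zero effect size.
    event_min_hours: float = 28.0
    event_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    uei_short_prob: float = 0.3        # intubations failing the 48-h rule
    signature_lead_hours: float = 12.0
    effect_size: float = 2.0           # standardized drift magnitude delta
    ar1_autocorr: float = 0.8          # per hour
    vital_gap_mean_hours: float = 1.0
    lab_gap_mean_hours: float = 8.0
    vitals: dict = field(default_factory=lambda: dict(DEFAULT_VITALS))
    labs: dict = field(default_factory=lambda: dict(DEFAULT_LABS))
    medications: dict = field(
        default_factory=lambda: dict(DEFAULT_MEDICATIONS))
    med_event_multiplier: float = 3.0
    period_start: str = "2021-01-01"
    period_days: int = 1095
    seed: int = 0


@dataclass
class CohortData:
    admissions: pd.DataFrame
    events: pd.DataFrame
    observations: pd.DataFrame
    ground_truth: dict


def _round_minute(ts: pd.Timestamp) -> pd.Timestamp:
    return pd.Timestamp(ts).floor("min")


def _sample_age(rng) -> float:
    probs = np.array([c[2] for c in AGE_CATEGORIES])
    i = rng.choice(len(AGE_CATEGORIES), p=probs / probs.sum())
    lo, hi, _ = AGE_CATEGORIES[i]
    return float(rng.uniform(lo, hi))


def _ar1_series(rng, times_h, scale, rho):
    """Continuous-time AR(1) noise sampled at irregular times."""
    x = np.empty(len(times_h))
    if len(x) == 0:
        return x
    x[0] = rng.normal(0.0, scale)
    for i in range(1, len(x)):
        dt = times_h[i] - times_h[i - 1]
        r = rho ** dt
        x[i] = r * x[i - 1] + rng.normal(0.0, scale * math.sqrt(1 - r * r))
    return x


def _signature_ramp(times_h, event_hs, lead_h):
    """Drift multiplier in [0, 1]: linear ramp over the lead window.

    Rises from 0 at event - lead to 1 at the event, then relaxes back to 0
    over the 6 h after it (post-intervention stabilization); multiple
    events combine by maximum.
    """
    ramp = np.zeros(len(times_h))
    for e in event_hs:
        up = np.clip((times_h - (e - lead_h)) / lead_h, 0.0, 1.0)
        up[times_h > e] = 0.0
        down = np.clip(1.0 - (times_h - e) / 6.0, 0.0, 1.0)
        down[times_h <= e] = 0.0
        ramp = np.maximum(ramp, np.maximum(up, down))
    return ramp


def _poisson_times(rng, rate_per_h, duration_h, event_hs, lead_h, mult):
    """Inhomogeneous Poisson stream via thinning; rate multiplied pre-event."""
    peak = rate_per_h * max(1.0, mult)
    if peak <= 0:
        return np.empty(0)
    t, out = 0.0, []
    while True:
        t += rng.exponential(1.0 / peak)
        if t >= duration_h:
            break
        in_window = any(e - lead_h <= t < e for e in event_hs)
        rate = rate_per_h * (mult if in_window else 1.0)
        if rng.random() < rate / peak:
            out.append(t)
    return np.asarray(out)


def generate_cohort(config: SyntheticConfig) -> CohortData:
    """Generate admissions.csv / events.csv / observations.csv content.

    Fully reproducible per seed: each admission draws from its own hashed
    random stream, so editing one patient never reshuffles another.
    """
    cfg = config
    if cfg.signature_lead_hours > cfg.min_stay_hours:
        raise ValueError("signature lead exceeds the minimum stay length")
    master = np.random.default_rng(cfg.seed)
    period_start = pd.Timestamp(cfg.period_start)

    adm_rows, ev_rows, obs_rows = [], [], []
    truth_admissions = {}

    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        prng = admission_rng(cfg.seed, pid, "patient")
        age = _sample_age(prng)
        demo = {col: levels[prng.choice(len(levels), p=np.asarray(probs)
                                        / np.sum(probs))]
                for col, (levels, probs) in DEMOGRAPHIC_MARGINALS.items()}

        n_adm = 1 + (1 if prng.random() < cfg.readmission_prob else 0)
        prev_end, prev_enc = None, None
        for a in range(n_adm):
            aid = f"{pid}A{a}"
            rng = admission_rng(cfg.seed, aid, "admission")
            if cfg.emit_short_stays and rng.random() < cfg.short_stay_prob:
                stay_h = float(rng.uniform(4.0, cfg.min_stay_hours - 0.5))
            else:
                stay_h = float(np.exp(rng.normal(
                    math.log(cfg.stay_median_hours), cfg.stay_sigma_log)))
                stay_h = max(stay_h, cfg.min_stay_hours)
            if a == 0 or prev_end is None:
                start = period_start + pd.Timedelta(
                    hours=float(rng.uniform(0, cfg.period_days * 24.0)))
                enc_id = f"{pid}E{a}"
                enc_start = start - pd.Timedelta(
                    hours=float(rng.uniform(0.0, 48.0)))
            elif rng.random() < cfg.same_encounter_prob:
                start = prev_end + pd.Timedelta(
                    hours=float(rng.uniform(4.0, 48.0)))
                enc_id, enc_start = prev_enc
            else:
                start = prev_end + pd.Timedelta(
                    hours=float(rng.uniform(24.0 * 7, 24.0 * 60)))
                enc_id = f"{pid}E{a}"
                enc_start = start - pd.Timedelta(
                    hours=float(rng.uniform(0.0, 48.0)))
            start = _round_minute(start)
            enc_start = _round_minute(min(enc_start, start))
            end = _round_minute(start + pd.Timedelta(hours=stay_h))
            stay_h = (end - start).total_seconds() / 3600.0
            prev_end, prev_enc = end, (enc_id, enc_start)

            adm_rows.append({
                "patient_id": pid, "admission_id": aid,
                "encounter_id": enc_id, "encounter_start": enc_start,
                "picu_start": start, "picu_end": end,
                "age_years": round(age, 3), **demo})

            # --- events ----------------------------------------------------
            event_hs, truth_events = [], []
            if (cfg.event_prob > 0
                    and stay_h >= cfg.event_min_hours + 2.0
                    and rng.random() < cfg.event_prob):
                n_events = 1 + (1 if rng.random() < cfg.second_event_prob
                                else 0)
                types = list(cfg.event_mix)
                probs = np.array([cfg.event_mix[t] for t in types])
                probs = probs / probs.sum()
                for _ in range(n_events):
                    e_h = float(rng.uniform(cfg.event_min_hours, stay_h - 2.0))
                    etype = types[rng.choice(len(types), p=probs)]
                    e_time = _round_minute(start + pd.Timedelta(hours=e_h))
                    e_h = (e_time - start).total_seconds() / 3600.0
                    ext_time, confirmed_type = pd.NaT, etype
                    duration_h = None
                    if etype == "INTUBATION":
                        if rng.random() < cfg.uei_short_prob:
                            duration_h = float(rng.uniform(6.0, 47.0))
                        else:
                            duration_h = 48.0 + float(rng.exponential(72.0))
                        ext = e_time + pd.Timedelta(hours=duration_h)
                        if ext > end:
                            ext_time = pd.NaT  # still intubated at discharge
                            confirmed_type = "UEI"
                        else:
                            ext_time = _round_minute(ext)
                            duration_h = ((ext_time - e_time)
                                          .total_seconds() / 3600.0)
                            confirmed_type = ("UEI" if duration_h >= 48.0
                                              else None)
                    ev_rows.append({"admission_id": aid, "event_type": etype,
                                    "event_time": e_time,
                                    "extubation_time": ext_time})
                    event_hs.append(e_h)
                    truth_events.append({
                        "time": e_time.isoformat(), "raw_type": etype,
                        "confirmed_type": confirmed_type,
                        "intubation_hours": duration_h})
            truth_admissions[aid] = {
                "events": truth_events,
                "signature_onsets": [
                    (start + pd.Timedelta(
                        hours=e - cfg.signature_lead_hours)).isoformat()
                    for e in event_hs],
                "stay_hours": stay_h,
            }

            # --- observations ---------------------------------------------
            def _emit(var, cat, times_h, values):
                obs_time = start + pd.to_timedelta(
                    np.floor(np.asarray(times_h) * 60.0), unit="m")
                obs_rows.append(pd.DataFrame({
                    "admission_id": aid, "obs_time": obs_time,
                    "variable": var,
                    "value": np.round(np.asarray(values, dtype=float), 3),
                    "category": cat}))

            for cat, variables, gap_mean in (
                    ("vital", cfg.vitals, cfg.vital_gap_mean_hours),
                    ("laboratory", cfg.labs, cfg.lab_gap_mean_hours)):
                for var, (baseline, scale, sign) in variables.items():
                    vrng = admission_rng(cfg.seed, aid, f"obs:{var}")
                    gaps = vrng.exponential(
                        gap_mean, size=int(stay_h / gap_mean * 3) + 10)
                    times_h = np.cumsum(gaps)
                    times_h = times_h[times_h < stay_h]
                    noise = _ar1_series(vrng, times_h, scale,
                                        cfg.ar1_autocorr)
                    patient_shift = vrng.normal(0.0, 0.5 * scale)
                    drift = (cfg.effect_size * scale * sign
                             * _signature_ramp(times_h, event_hs,
                                               cfg.signature_lead_hours))
                    _emit(var, cat, times_h,
                          baseline + patient_shift + noise + drift)
            # the medication intensification is part of the deterioration
            # signature: a zero effect size disables it along with the
            # vital/lab drift, so delta = 0 is a true null
            med_mult = (cfg.med_event_multiplier if cfg.effect_size > 0
                        else 1.0)
            for med, rate in cfg.medications.items():
                mrng = admission_rng(cfg.seed, aid, f"med:{med}")
                times_h = _poisson_times(
                    mrng, rate, stay_h, event_hs,
                    cfg.signature_lead_hours, med_mult)
                if len(times_h):
                    _emit(med, "medication", times_h,
                          np.ones(len(times_h)))

    admissions = pd.DataFrame(adm_rows)
    events = pd.DataFrame(
        ev_rows, columns=["admission_id", "event_type", "event_time",
                          "extubation_time"])
    if obs_rows:
        observations = pd.concat(obs_rows, ignore_index=True)
    else:
        observations = pd.DataFrame(
            columns=["admission_id", "obs_time", "variable", "value",
                     "category"])
    observations = observations.sort_values(
        ["admission_id", "obs_time", "variable"],
        kind="stable").reset_index(drop=True)
    ground_truth = {
        "config": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in asdict(cfg).items()},
        "admissions": truth_admissions,
    }
    return CohortData(admissions=admissions, events=events,
                      observations=observations, ground_truth=ground_truth)


def generate_bernoulli_scores(admissions: pd.DataFrame,
                              interval_hours: float, q: float, seed: int,
                              reference_threshold: float = 0.5
                              ) -> pd.DataFrame:
    """Scores that exceed a reference threshold i.i.d. with probability q.

    An oracle input for the alert simulator: on a Δ-spaced grid each
    probability lands in [threshold, 1] with probability q and in
    [0, threshold) otherwise, independently.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    rows = []
    for _, r in admissions.iterrows():
        grid = prediction_grid(r["picu_start"], r["picu_end"],
                               interval_hours)
        rng = admission_rng(seed, r["admission_id"], "bernoulli-scores")
        hot = rng.random(len(grid)) < q
        u = rng.random(len(grid))
        probs = np.where(hot,
                         reference_threshold + (1 - reference_threshold) * u,
                         reference_threshold * u)
        for t, p in zip(grid, probs):
            rows.append({"admission_id": r["admission_id"], "time": t,
                         "probability": float(p)})
    return pd.DataFrame(rows, columns=["admission_id", "time",
                                       "probability"])


def expected_alert_rate(interval_hours: float, q: float,
                        refractory_hours: float) -> float:
    """Renewal-theory alerts per patient-day on i.i.d. exceedance scores.

    One renewal cycle is the refractory span rounded up to the grid
    (at least one interval) plus the geometric wait for the next
    exceedance: 24 / (Δ·max(1, ceil(R/Δ)) + Δ·(1/q - 1)).
    """
    if interval_hours <= 0:
        raise ValueError("interval must be positive")
    if q == 0:
        return 0.0
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    d = interval_hours
    cycle = d * max(1, math.ceil(refractory_hours / d)) + d * (1.0 / q - 1.0)
    return 24.0 / cycle
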