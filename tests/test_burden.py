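"""Alert simulation and burden metrics vs. a minute-resolution oracle."""

import numpy as np
import pandas as pd
import pytest

from cdewatch import burden as bd
from conftest import ts, make_admission
from _oracles import minute_loop_alerts


def policy(**kw):
    defaults = dict(interval_hours=1.0, threshold=0.5,
                    refractory_hours=0.0, censor_hours=24.0,
                    window_hours=24.0)
    defaults.update(kw)
    return bd.AlertPolicy(**defaults)


def hourly(probs):
    return np.arange(len(probs), dtype=float), np.asarray(probs, float)


class TestPredictionGrid:
    def test_twelve_hourly_grid(self):
        grid = bd.prediction_grid(ts(0), ts(25), 12.0)
        assert [(g - ts(0)).total_seconds() / 3600 for g in grid] == \
            [0.0, 12.0, 24.0]

    def test_hourly_grid_includes_endpoint(self):
        assert len(bd.prediction_grid(ts(0), ts(25), 1.0)) == 26

    def test_interval_beyond_stay(self):
        assert len(bd.prediction_grid(ts(0), ts(25), 48.0)) == 1


class TestSimulateAlerts:
    def test_forced_cadence_with_refractory(self):
        grid, probs = hourly([1.0] * 37)  # 36-h stay, hourly
        alerts = bd.simulate_alerts_hours(
            grid, probs, [], policy(refractory_hours=12.0))
        assert list(alerts) == [0.0, 12.0, 24.0, 36.0]

    def test_below_threshold_never_fires(self):
        grid, probs = hourly([0.4] * 20)
        assert len(bd.simulate_alerts_hours(grid, probs, [], policy())) == 0

    def test_censoring_after_event(self):
        # 48-h stay, hourly, no refractory, event at 20 h, censor 24 h:
        # alerts at hours 0-19 then from 44 (censor half-open) to 48
        grid, probs = hourly([1.0] * 49)
        alerts = bd.simulate_alerts_hours(grid, probs, [20.0], policy())
        assert list(alerts) == list(range(20)) + [44, 45, 46, 47, 48]

    def test_threshold_boundary_inclusive_vs_strict(self):
        grid, probs = hourly([0.5, 0.4, 0.5])
        assert len(bd.simulate_alerts_hours(grid, probs, [], policy())) == 2
        assert len(bd.simulate_alerts_hours(
            grid, probs, [], policy(strict=True))) == 0

    def test_refractory_boundary_grid_point_eligible(self):
        # first grid point at exactly a + R fires again
        grid, probs = hourly([1.0] * 7)
        alerts = bd.simulate_alerts_hours(
            grid, probs, [], policy(refractory_hours=3.0))
        assert list(alerts) == [0.0, 3.0, 6.0]

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            bd.simulate_alerts_hours([2.0, 1.0], [1.0, 1.0], [], policy())

    def test_matches_minute_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            dt = float(rng.choice([1.0, 2.0, 12.0]))
            stay = float(rng.integers(12, 73))
            grid = np.arange(0.0, stay + 1e-9, dt)
            probs = rng.random(len(grid)).round(2)
            events = np.sort(rng.uniform(0, stay,
                                         rng.integers(0, 4))).round(2)
            events = np.round(events * 60) / 60  # whole minutes
            pol = policy(threshold=float(rng.choice([0.2, 0.5, 0.8])),
                         refractory_hours=float(rng.choice([0, 12, 24])),
                         censor_hours=float(rng.choice([0, 24])))
            fast = bd.simulate_alerts_hours(grid, probs, events, pol)
            slow = minute_loop_alerts(grid, probs, events, pol.threshold,
                                      pol.refractory_hours,
                                      pol.censor_hours)
            np.testing.assert_array_equal(fast, slow)


class TestDetection:
    def _alerts(self, aid_hours):
        return pd.DataFrame([{"admission_id": a, "alert_time": ts(h),
                              "probability": 1.0} for a, h in aid_hours])

    def _events(self, aid_hours):
        return pd.DataFrame([{"admission_id": a, "event_type": "CPR",
                              "event_time": ts(h)} for a, h in aid_hours])

    def test_alert_outside_window_missed(self):
        frac, flags = bd.detection_fraction(
            self._alerts([("A1", 0.0)]), self._events([("A1", 25.0)]))
        assert frac == 0.0 and not flags["detected"].any()

    def test_alert_inside_window_detected(self):
        frac, _ = bd.detection_fraction(
            self._alerts([("A1", 15.0)]), self._events([("A1", 25.0)]))
        assert frac == 1.0

    def test_alert_at_event_instant_not_advance_warning(self):
        frac, _ = bd.detection_fraction(
            self._alerts([("A1", 25.0)]), self._events([("A1", 25.0)]))
        assert frac == 0.0

    def test_no_events_not_applicable(self):
        frac, _ = bd.detection_fraction(self._alerts([("A1", 1.0)]),
                                        self._events([]))
        assert np.isnan(frac)

    def test_matches_exhaustive_pair_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            alerts = self._alerts([("A1", float(h))
                                   for h in rng.uniform(0, 72, 6)])
            events = self._events([("A1", float(h))
                                   for h in rng.uniform(0, 72, 3)])
            _, flags = bd.detection_fraction(alerts, events, 24.0)
            for _, e in flags.iterrows():
                expect = any(
                    e["event_time"] - pd.Timedelta(hours=24)
                    <= a < e["event_time"]
                    for a in alerts["alert_time"])
                assert e["detected"] == expect


class TestBurdenMetrics:
    def _setup(self):
        adm = pd.DataFrame([
            make_admission(aid="A1", start_h=0, end_h=120),
            make_admission(aid="A2", pid="P2", start_h=0, end_h=120)])
        return adm

    def test_alerts_per_patient_day(self):
        adm = self._setup()  # 240 h = 10 patient-days
        alerts = pd.DataFrame([
            {"admission_id": "A1", "alert_time": ts(5), "probability": 1.0},
            {"admission_id": "A2", "alert_time": ts(9), "probability": 1.0}])
        rep = bd.burden_metrics(alerts, pd.DataFrame(
            columns=["admission_id", "event_type", "event_time"]), adm,
            policy())
        assert rep.alerts_per_patient_day == pytest.approx(0.2)
        assert np.isnan(rep.detection_fraction)

    def test_admission_nna(self):
        rows = [make_admission(aid=f"A{i}", pid=f"P{i}", end_h=48)
                for i in range(10)]
        adm = pd.DataFrame(rows)
        alerts = pd.DataFrame([
            {"admission_id": f"A{i}", "alert_time": ts(20),
             "probability": 1.0} for i in range(10)])
        events = pd.DataFrame([
            {"admission_id": f"A{i}", "event_type": "CPR",
             "event_time": ts(30)} for i in range(5)])
        rep = bd.burden_metrics(alerts, events, adm, policy())
        assert rep.admission_nna == pytest.approx(2.0)

    def test_lead_time_earliest_convention(self):
        adm = pd.DataFrame([make_admission(aid="A1", end_h=60)])
        alerts = pd.DataFrame([
            {"admission_id": "A1", "alert_time": ts(20), "probability": 1.0},
            {"admission_id": "A1", "alert_time": ts(37), "probability": 1.0}])
        events = pd.DataFrame([{"admission_id": "A1", "event_type": "CPR",
                                "event_time": ts(40)}])
        rep = bd.burden_metrics(alerts, events, adm, policy())
        assert rep.lead_median_hours == pytest.approx(20.0)
        rep_late = bd.burden_metrics(
            alerts, events, adm, policy(lead_convention="latest"))
        assert rep_late.lead_median_hours == pytest.approx(3.0)

    def test_nna_is_reciprocal_admission_ppv(self):
        # window = full stay, at most one event per admission
        rng = np.random.default_rng(2)
        rows, alert_rows, event_rows = [], [], []
        for i in range(30):
            rows.append(make_admission(aid=f"A{i}", pid=f"P{i}", end_h=100))
            if rng.random() < 0.7:
                alert_rows.append({"admission_id": f"A{i}",
                                   "alert_time": ts(rng.uniform(1, 50)),
                                   "probability": 1.0})
            if rng.random() < 0.4:
                event_rows.append({"admission_id": f"A{i}",
                                   "event_type": "CPR",
                                   "event_time": ts(rng.uniform(51, 99))})
        adm = pd.DataFrame(rows)
        alerts = pd.DataFrame(alert_rows)
        events = pd.DataFrame(event_rows)
        rep = bd.burden_metrics(alerts, events, adm,
                                policy(window_hours=100.0))
        flagged = set(alerts["admission_id"])
        detected = {e["admission_id"] for e in event_rows
                    if e["admission_id"] in flagged}
        ppv = len(detected) / len(flagged)
        assert rep.admission_nna == pytest.approx(1.0 / ppv)


class TestSweepAndSelection:
    def _scores(self, seed=0, n_adm=20, stay_h=72):
        rng = np.random.default_rng(seed)
        rows, adm_rows, ev_rows = [], [], []
        for i in range(n_adm):
            aid = f"A{i}"
            adm_rows.append(make_admission(aid=aid, pid=f"P{i}",
                                           end_h=stay_h))
            for h in range(stay_h + 1):
                rows.append({"admission_id": aid, "time": ts(h),
                             "probability": float(rng.random())})
            if rng.random() < 0.4:
                ev_rows.append({"admission_id": aid, "event_type": "CPR",
                                "event_time": ts(float(
                                    rng.uniform(16, stay_h - 2)))})
        return (pd.DataFrame(rows), pd.DataFrame(
            ev_rows, columns=["admission_id", "event_type", "event_time"]),
            pd.DataFrame(adm_rows))

    def test_extreme_thresholds(self):
        scores, events, adm = self._scores()
        curve = bd.sweep_thresholds(scores, events, adm,
                                    policy(refractory_hours=12.0),
                                    [0.0, 1.0 - 1e-9])
        low, high = curve.reports
        assert low.n_alerts > 0 and low.detection_fraction == 1.0
        assert high.n_alerts == 0 and high.detection_fraction == 0.0

    def test_burden_nonincreasing_in_threshold(self):
        scores, events, adm = self._scores(seed=3)
        curve = bd.sweep_thresholds(scores, events, adm,
                                    policy(refractory_hours=12.0),
                                    [0.3, 0.6])
        assert (curve.reports[0].alerts_per_patient_day
                >= curve.reports[1].alerts_per_patient_day)

    def test_threshold_for_detection(self):
        scores, events, adm = self._scores(seed=4)
        grid = np.linspace(0.0, 0.95, 15)
        curve = bd.sweep_thresholds(scores, events, adm, policy(), grid)
        thr, rep = bd.threshold_for_detection(curve, 0.5)
        assert rep.detection_fraction >= 0.5
        # largest qualifying threshold: the next one (if any) fails
        i = list(curve.thresholds).index(thr)
        for t2, r2 in zip(curve.thresholds[i + 1:], curve.reports[i + 1:]):
            assert r2.detection_fraction < 0.5

    def test_target_zero_returns_largest_threshold(self):
        scores, events, adm = self._scores(seed=5)
        curve = bd.sweep_thresholds(scores, events, adm, policy(),
                                    [0.2, 0.8])
        thr, _ = bd.threshold_for_detection(curve, 0.0)
        assert thr == 0.8

    def test_unreachable_target(self):
        scores, events, adm = self._scores(seed=6)
        curve = bd.sweep_thresholds(scores, events, adm, policy(),
                                    [1.0 - 1e-9])
        with pytest.raises(bd.UnreachableDetectionError):
            bd.threshold_for_detection(curve, 0.8)


class TestBinaryTool:
    def _indicator(self, values, aid="A1"):
        return pd.DataFrame([{"admission_id": aid, "time": ts(float(h)),
                              "probability": float(v)}
                             for h, v in enumerate(values)])

    def test_all_zero_indicator(self):
        adm = pd.DataFrame([make_admission(aid="A1", end_h=36)])
        rep = bd.binary_tool_burden(
            self._indicator([0] * 37), pd.DataFrame(
                columns=["admission_id", "event_type", "event_time"]),
            adm, policy())
        assert rep.n_alerts == 0

    def test_all_one_matches_probability_one(self):
        adm = pd.DataFrame([make_admission(aid="A1", end_h=36)])
        events = pd.DataFrame(columns=["admission_id", "event_type",
                                       "event_time"])
        pol = policy(refractory_hours=12.0)
        rep = bd.binary_tool_burden(self._indicator([1] * 37), events, adm,
                                    pol)
        alerts = bd.simulate_alerts(self._indicator([1.0] * 37), events,
                                    adm, pol)
        assert rep.n_alerts == len(alerts) == 4

    def test_nonbinary_rejected(self):
        adm = pd.DataFrame([make_admission(aid="A1", end_h=36)])
        with pytest.raises(ValueError, match="0/1"):
            bd.binary_tool_burden(self._indicator([0.3] * 37),
                                  pd.DataFrame(columns=[
                                      "admission_id", "event_type",
                                      "event_time"]), adm, policy())

    def test_random_binary_equals_generic_path(self):
        rng = np.random.default_rng(7)
        adm = pd.DataFrame([make_admission(aid="A1", end_h=72)])
        vals = (rng.random(73) < 0.3).astype(int)
        events = pd.DataFrame([{"admission_id": "A1", "event_type": "CPR",
                                "event_time": ts(40.0)}])
        pol = policy(refractory_hours=12.0)
        rep_bin = bd.binary_tool_burden(self._indicator(vals), events, adm,
                                        pol)
        alerts = bd.simulate_alerts(self._indicator(vals), events, adm,
                                    bd.AlertPolicy(**{**pol.__dict__,
                                                      "threshold": 0.5}))
        rep_gen = bd.burden_metrics(alerts, events, adm, pol)
        assert rep_bin.n_alerts == rep_gen.n_alerts
        assert rep_bin.detection_fraction == rep_gen.detection_fraction
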