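import math

import numpy as np
import pytest

from mewskit.alarms import EvalConfig, classify_alarms, generate_alarms
from mewskit.cohort import Cohort, PatientRecord
from mewskit.event_level import (
    BootstrapEstimate,
    SensitivityResult,
    alarm_burden,
    bootstrap_derived_metrics,
    bootstrap_fpr,
    exact_window_hit_probability,
    time_dependent_sensitivity,
    time_profiles,
    wdr,
)
from mewskit.patient_level import metrics_from_confusion, patient_confusion

from conftest import make_series, random_series_cohort


def _case(pid, t_event, alarm_like_totals, times=None):
    rec = PatientRecord(patient_id=pid, group="case", t_end=t_event, samples={})
    times = np.asarray(
        times if times is not None else np.arange(1, len(alarm_like_totals) + 1),
        dtype=float,
    )
    return rec, make_series(pid, times, alarm_like_totals)


def _control(pid, t_end, times, totals):
    rec = PatientRecord(patient_id=pid, group="control", t_end=t_end, samples={})
    return rec, make_series(pid, np.asarray(times, dtype=float), totals)


class TestSensitivity:
    def test_half_predicted(self):
        cfg = EvalConfig(k=4, tau=12.0, tau0=0.0)
        recs, series = [], {}
        # two cases alarm inside the horizon, two never alarm
        for pid, totals in (
            ("a", [9]), ("b", [9]), ("c", [0]), ("d", [0]),
        ):
            rec, s = _case(pid, t_event=20.0, alarm_like_totals=totals, times=[15.0])
            recs.append(rec)
            series[pid] = s
        res = time_dependent_sensitivity(recs, series, cfg)
        assert res.S == 0.5 and res.N_events == 4 and res.N_predicted_events == 2

    def test_short_stay_excluded(self):
        cfg = EvalConfig(k=4, tau=12.0, tau0=2.0)
        rec, s = _case("short", t_event=10.0, alarm_like_totals=[9], times=[5.0])
        res = time_dependent_sensitivity([rec], {"short": s}, cfg)
        assert res.N_events == 0 and res.excluded == ("short",)
        assert math.isnan(res.S) and res.empty

    def test_large_lead_time_empties_window(self):
        # all alarms in the last 2 h; a 3 h lead time pushes the horizon before them
        rec, s = _case("x", t_event=40.0, alarm_like_totals=[9, 9], times=[38.5, 39.5])
        res = time_dependent_sensitivity([rec], {"x": s}, EvalConfig(k=4, tau=12, tau0=3))
        assert res.S == 0.0

    def test_full_stay_horizon_equals_patient_tpr(self, rng):
        """With the horizon spanning the whole stay, S collapses to TPR."""
        cohort, series = random_series_cohort(rng, n_cases=7, n_controls=5)
        cfg = EvalConfig(k=4, tau=None, tau0=0.0)
        res = time_dependent_sensitivity(cohort.cases, series, cfg)
        tpr = metrics_from_confusion(patient_confusion(cohort, series, 4)).TPR
        assert res.S == pytest.approx(tpr, abs=0)


class TestBootstrapFPR:
    def test_silent_control(self):
        cfg = EvalConfig(k=4, tau=5.0, M=50, seed=1)
        rec, s = _control("q", 30.0, [1.0, 10.0], [0, 2])
        est = bootstrap_fpr([rec], {"q": s}, cfg)
        assert est.mean == 0.0 and est.std == 0.0

    def test_saturated_control(self):
        cfg = EvalConfig(k=4, tau=5.0, M=50, seed=1)
        times = np.arange(0.0, 30.5, 0.5)
        rec, s = _control("q", 30.0, times, np.full(len(times), 9))
        est = bootstrap_fpr([rec], {"q": s}, cfg)
        assert est.mean == 1.0

    def test_short_recordings_excluded(self):
        cfg = EvalConfig(k=4, tau=12.0, M=10, seed=0)
        r1, s1 = _control("short", 5.0, [1.0], [9])
        r2, s2 = _control("long", 40.0, [1.0], [9])
        est = bootstrap_fpr([r1, r2], {"short": s1, "long": s2}, cfg)
        assert est.excluded == ("short",)
        assert est.control_ids == ("long",)
        with pytest.raises(ValueError):
            bootstrap_fpr([r1], {"short": s1}, cfg)

    def test_seed_determinism(self):
        cfg = EvalConfig(k=4, tau=5.0, M=200, seed=42)
        rec, s = _control("q", 60.0, [3.0, 20.0, 44.0], [9, 9, 9])
        a = bootstrap_fpr([rec], {"q": s}, cfg)
        b = bootstrap_fpr([rec], {"q": s}, cfg)
        assert np.array_equal(a.hits, b.hits)
        assert a.mean == b.mean and a.std == b.std

    def test_mean_matches_exact_window_probability(self):
        """Monte-Carlo estimate vs closed-form window-hit probability on
        five controls with hand-placed alarms."""
        cfg = EvalConfig(k=4, tau=6.0, M=2000, seed=9)
        layouts = [
            (48.0, [10.0]),
            (48.0, [5.0, 6.0, 7.0]),
            (72.0, [1.0, 35.0, 70.0]),
            (24.0, []),
            (100.0, list(np.arange(10.0, 90.0, 4.0))),
        ]
        recs, series, exact = [], {}, []
        for i, (t_end, alarms) in enumerate(layouts):
            pid = f"c{i}"
            times = np.asarray(alarms, dtype=float)
            rec, s = _control(pid, t_end, times, np.full(len(times), 9))
            recs.append(rec)
            series[pid] = s
            exact.append(exact_window_hit_probability(times, t_end, cfg.tau))
        est = bootstrap_fpr(recs, series, cfg)
        p = np.array(exact)
        mc_se = math.sqrt(float(np.sum(p * (1 - p))) / (len(p) ** 2 * cfg.M))
        assert abs(est.mean - p.mean()) <= 3 * mc_se

    def test_variance_variants(self):
        cfg = EvalConfig(k=4, tau=6.0, M=100, seed=5)
        recs, series = [], {}
        for i, t_end in enumerate((30.0, 40.0, 50.0)):
            pid = f"c{i}"
            rec, s = _control(pid, t_end, [t_end / 2], [9])
            recs.append(rec)
            series[pid] = s
        prop = bootstrap_fpr(recs, series, cfg, variance="proportion")
        lit = bootstrap_fpr(recs, series, cfg, variance="literal")
        assert np.array_equal(prop.hits, lit.hits)
        # the literal deviation mixes a proportion with a count and is larger
        assert lit.std >= prop.std


class TestDerivedMetrics:
    def _boot(self, hits):
        hits = np.asarray(hits, dtype=np.int8)
        return BootstrapEstimate(
            mean=float(hits.mean()),
            std=0.0,
            M=hits.shape[1],
            per_window_counts=hits.sum(axis=0),
            hits=hits,
            control_ids=tuple(f"c{i}" for i in range(hits.shape[0])),
        )

    def test_silent_controls_give_perfect_precision(self):
        sens = SensitivityResult(S=1.0, N_predicted_events=3, N_events=3)
        panel = bootstrap_derived_metrics(sens, self._boot(np.zeros((4, 10))))
        assert panel["FPR"]["mean"] == 0.0
        assert panel["PPV"]["mean"] == 1.0

    def test_single_replicate_has_zero_std(self):
        sens = SensitivityResult(S=0.5, N_predicted_events=1, N_events=2)
        panel = bootstrap_derived_metrics(sens, self._boot([[1], [0]]))
        assert all(panel[m]["std"] == 0.0 for m in panel)

    def test_replicate_confusion_arithmetic(self):
        # 2 predicted of 3 events; replicate FP counts are 1 and 3 of 4 controls
        sens = SensitivityResult(S=2 / 3, N_predicted_events=2, N_events=3)
        hits = np.array([[1, 1], [0, 1], [0, 1], [0, 0]])
        panel = bootstrap_derived_metrics(sens, self._boot(hits))
        fpr = np.array([1 / 4, 3 / 4])
        ppv = np.array([2 / 3, 2 / 5])
        acc = np.array([(2 + 3) / 7, (2 + 1) / 7])
        assert panel["FPR"]["mean"] == pytest.approx(fpr.mean())
        assert panel["PPV"]["mean"] == pytest.approx(ppv.mean())
        assert panel["ACC"]["mean"] == pytest.approx(acc.mean())
        assert panel["PPV"]["std"] == pytest.approx(ppv.std(ddof=1))


class TestWDR:
    def test_no_false_positives_gives_one(self):
        hits = np.zeros((5, 20), dtype=np.int8)
        boot = TestDerivedMetrics()._boot(hits)
        res = wdr(10, boot)
        assert res.mean == 1.0 and res.std == 0.0

    def test_matches_direct_formula(self, rng):
        hits = (rng.random((8, 100)) < 0.3).astype(np.int8)
        boot = TestDerivedMetrics()._boot(hits)
        n_pred = 6
        res = wdr(n_pred, boot)
        mu_fp = hits.mean(axis=1).sum()
        assert res.mean == pytest.approx((n_pred + mu_fp) / n_pred)
        assert res.mean == pytest.approx(1 + res.mu_FP / res.N_case_predicted)
        sigma = hits.std(axis=1, ddof=1)
        assert res.std == pytest.approx(math.sqrt(float((sigma**2).sum())) / n_pred)

    def test_zero_predictions_flagged(self):
        boot = TestDerivedMetrics()._boot(np.zeros((2, 5), dtype=np.int8))
        res = wdr(0, boot)
        assert math.isnan(res.mean) and math.isnan(res.std)


class TestBurden:
    def test_control_rates(self):
        cfg = EvalConfig(k=4, tau=12.0, tau0=0.0)
        times = np.linspace(0.5, 24, 48)
        totals = np.zeros(48, dtype=int)
        totals[:6] = 9  # 6 alarms
        rec, s = _control("q", 24.0, times, totals)
        aset = classify_alarms(generate_alarms(s, cfg.k), rec, cfg)
        b = alarm_burden(rec, s, aset, cfg)
        assert b.r == pytest.approx(0.25)
        assert b.rho == pytest.approx(0.125)
        assert b.r0 == b.r and b.rho0 == b.rho  # every control alarm is false

    def test_case_false_alarm_rate_subtracts_horizon(self):
        cfg = EvalConfig(k=4, tau=12.0, tau0=0.0)
        # 4 early alarms well before the horizon of a 36 h case stay
        rec, s = _case("c", 36.0, [9, 9, 9, 9], times=[2, 4, 6, 8])
        aset = classify_alarms(generate_alarms(s, cfg.k), rec, cfg)
        b = alarm_burden(rec, s, aset, cfg)
        assert b.N_false == 4
        assert b.r0 == pytest.approx(4 / 24)

    def test_zero_horizon_makes_all_alarms_false(self, rng):
        cfg = EvalConfig(k=4, tau=0.0, tau0=0.0)
        times = np.sort(rng.uniform(0, 30, 25))
        totals = rng.integers(0, 15, len(times))
        rec, s = _case("c", 30.0, totals, times=times)
        aset = classify_alarms(generate_alarms(s, cfg.k), rec, cfg)
        b = alarm_burden(rec, s, aset, cfg)
        assert b.r0 == pytest.approx(b.r)
        assert b.rho0 == pytest.approx(b.rho)

    def test_recording_not_longer_than_horizon_flagged(self):
        cfg = EvalConfig(k=4, tau=12.0, tau0=0.0)
        rec, s = _case("c", 10.0, [9], times=[5.0])
        aset = classify_alarms(generate_alarms(s, cfg.k), rec, cfg)
        b = alarm_burden(rec, s, aset, cfg)
        assert math.isnan(b.r0)


class TestTimeProfiles:
    def _aset(self, pid, classes):
        from mewskit.alarms import AlarmSet

        return AlarmSet(
            patient_id=pid,
            group="case",
            times=np.arange(len(classes), dtype=float),
            classes=np.array(classes, dtype=object),
        )

    def test_proportions(self):
        aset = self._aset("a", ["early"] * 3 + ["on_time"])
        per_alarm, per_event = time_profiles([aset])
        assert per_alarm.values["early"] == pytest.approx(0.75)
        assert per_alarm.values["on_time"] == pytest.approx(0.25)
        assert per_alarm.values["late"] == 0.0

    def test_missed_events_counted(self):
        a = self._aset("a", ["on_time"])
        b = self._aset("b", ["early", "late"])
        per_alarm, per_event = time_profiles([a, b])
        assert per_alarm.counts["missed_events"] == 1
        assert per_event.values["missed_events"] == pytest.approx(0.5)

    def test_per_event_normalisation_identity(self, rng):
        sets = []
        for i in range(5):
            classes = rng.choice(["early", "on_time", "late"], size=rng.integers(1, 10))
            sets.append(self._aset(f"p{i}", list(classes)))
        per_alarm, per_event = time_profiles(sets)
        for cls in ("early", "on_time", "late"):
            assert per_event.values[cls] * per_event.N_events == pytest.approx(
                per_event.counts[cls]
            )
        assert sum(per_alarm.values[c] for c in ("early", "on_time", "late")) == (
            pytest.approx(1.0)
        )


class TestMonotonicity:
    def test_sensitivity_and_burden_non_increasing_in_k(self, rng):
        cohort, series = random_series_cohort(rng, n_cases=6, n_controls=8)
        prev = None
        for k in range(14):
            cfg = EvalConfig(k=k, tau=5.0, tau0=0.0)
            s = time_dependent_sensitivity(cohort.cases, series, cfg)
            burdens = []
            for rec in cohort:
                sr = series[rec.patient_id]
                aset = classify_alarms(generate_alarms(sr, k), rec, cfg)
                burdens.append(alarm_burden(rec, sr, aset, cfg))
            cur = (
                s.S if not math.isnan(s.S) else 0.0,
                float(np.nansum([b.r for b in burdens])),
                float(np.nansum([b.rho for b in burdens])),
                float(np.nansum([b.r0 for b in burdens])),
                float(np.nansum([b.rho0 for b in burdens])),
            )
            if prev is not None:
                assert all(a >= b - 1e-12 for a, b in zip(prev, cur))
            prev = cur
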