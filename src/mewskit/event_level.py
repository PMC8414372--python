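"""Event-level evaluation of threshold alarms.

Unlike the patient-level scheme, which only asks whether the score ever
crossed the threshold, the event-level scheme asks *when*.  It provides:

* time-dependent sensitivity S — the proportion of events preceded by
  at least one alarm inside the prediction horizon;
* a bootstrapped false-positive ratio (FPR) on controls — the expected
  fraction of control patients in whom a randomly placed horizon-length
  window contains an alarm — with replicate-derived accuracy, precision,
  NPV and F1;
* the work-up to detection ratio (WDR) with a standard deviation
  composed from the per-control bootstrap variability;
* per-patient alarm-burden metrics (alarm rate r, alarm proportion rho,
  and their false-alarm counterparts r0, rho0);
* pooled alarm time profiles over the early / on-time / late classes
  plus missed events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from mewskit.alarms import AlarmSet, EvalConfig, classify_alarms, generate_alarms
from mewskit.cohort import Cohort, PatientRecord
from mewskit.scoring import ScoreSeries

__all__ = [
    "SensitivityResult",
    "BootstrapEstimate",
    "WDRResult",
    "BurdenSummary",
    "TimeProfile",
    "time_dependent_sensitivity",
    "bootstrap_fpr",
    "bootstrap_derived_metrics",
    "wdr",
    "alarm_burden",
    "time_profiles",
    "exact_window_hit_probability",
]


# ---------------------------------------------------------------------------
# time-dependent sensitivity

@dataclass(frozen=True)
class SensitivityResult:
    """S = N_predicted_events / N_events over the eligible case group."""

    S: float
    N_predicted_events: int
    N_events: int
    excluded: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return self.N_events == 0


def time_dependent_sensitivity(
    cases: Iterable[PatientRecord],
    series_map: dict[str, ScoreSeries],
    config: EvalConfig,
) -> SensitivityResult:
    """Proportion of events with >= 1 alarm inside the prediction horizon.

    Case records whose pre-event stay is shorter than tau + tau0 are
    excluded (the horizon window does not fit, so a true prediction
    cannot be evaluated); their ids are reported.  An event is counted
    as predicted iff at least one alarm falls in the closed on-time
    window [t_event - tau0 - tau, t_event - tau0].
    """
    excluded: list[str] = []
    n_events = 0
    n_predicted = 0
    for rec in cases:
        if rec.group != "case":
            continue
        tau = config.resolve_tau(rec)
        if rec.t_end < tau + config.tau0:
            excluded.append(rec.patient_id)
            continue
        aset = classify_alarms(
            generate_alarms(series_map[rec.patient_id], config.k), rec, config
        )
        n_events += 1
        n_predicted += aset.n_on_time > 0
    s = n_predicted / n_events if n_events else math.nan
    return SensitivityResult(
        S=s,
        N_predicted_events=n_predicted,
        N_events=n_events,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# bootstrapped false-positive ratio

@dataclass
class BootstrapEstimate:
    """Bootstrap FPR estimate over N controls and M windows each.

    ``hits[i, j]`` is 1 when the j-th (time-ordered) window of control i
    contained at least one alarm.  ``per_window_counts[j]`` is the
    expected-false-positive count for window index j (sum over
    controls); the grand mean of ``hits`` is the FPR estimate.
    """

    mean: float
    std: float
    M: int
    per_window_counts: np.ndarray
    hits: np.ndarray  # shape (N, M), 0/1
    control_ids: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    @property
    def n_controls(self) -> int:
        return self.hits.shape[0]

    @property
    def mu_FP(self) -> float:
        """Expected number of false-positive controls, sum of per-control means."""
        return float(self.hits.mean(axis=1).sum())


def _window_hits(alarm_times: np.ndarray, starts: np.ndarray, tau: float) -> np.ndarray:
    """1 where the closed window [s, s+tau] contains an alarm."""
    a = np.sort(np.asarray(alarm_times, dtype=float))
    lo = np.searchsorted(a, starts, side="left")
    hi = np.searchsorted(a, starts + tau, side="right")
    return (hi > lo).astype(np.int8)


def bootstrap_fpr(
    controls: Iterable[PatientRecord],
    series_map: dict[str, ScoreSeries],
    config: EvalConfig,
    variance: Literal["proportion", "literal"] = "proportion",
) -> BootstrapEstimate:
    """Estimate the control-side false-positive ratio by random windows.

    For every control whose recording is at least as long as the horizon
    tau, M window start times are drawn uniformly on [0, T_i - tau],
    time-ordered, and indexed; shorter recordings are excluded and
    reported.  The estimate is the grand mean of the 0/1 window hits.

    The ``variance`` switch selects the per-window-index deviation used
    in the composed standard deviation: ``"proportion"`` (default) takes
    the sample standard deviation of the binary hits across controls —
    the standard binomial estimator — while ``"literal"`` measures the
    deviation of each binary hit from the window's false-positive
    *count*, which mixes a proportion with a count but is retained for
    comparability.  Either way the composition is the root mean square
    over window indices.
    """
    controls = [r for r in controls if r.group == "control"]
    tau = 0.0 if config.tau is None else config.tau
    eligible: list[PatientRecord] = []
    excluded: list[str] = []
    for rec in controls:
        if config.tau is not None and rec.t_end < tau:
            excluded.append(rec.patient_id)
        else:
            eligible.append(rec)
    if not eligible:
        raise ValueError("no control recording is at least as long as tau")

    rng = np.random.default_rng(config.seed)
    hits = np.empty((len(eligible), config.M), dtype=np.int8)
    for i, rec in enumerate(eligible):
        tau_i = config.resolve_tau(rec)
        alarms = generate_alarms(series_map[rec.patient_id], config.k)
        span = max(rec.t_end - tau_i, 0.0)
        starts = np.sort(rng.uniform(0.0, span, size=config.M))
        hits[i] = _window_hits(alarms, starts, tau_i)

    counts = hits.sum(axis=0)
    mean = float(hits.mean())
    n = hits.shape[0]
    if n > 1:
        h = hits.astype(float)
        if variance == "proportion":
            dev2 = ((h - h.mean(axis=0)) ** 2).sum(axis=0) / (n - 1)
        elif variance == "literal":
            dev2 = ((h - counts) ** 2).sum(axis=0) / (n - 1)
        else:
            raise ValueError(f"unknown variance variant {variance!r}")
        std = float(np.sqrt(dev2.mean()))
    else:
        std = 0.0
    return BootstrapEstimate(
        mean=mean,
        std=std,
        M=config.M,
        per_window_counts=counts.astype(int),
        hits=hits,
        control_ids=tuple(r.patient_id for r in eligible),
        excluded=tuple(excluded),
    )


def exact_window_hit_probability(
    alarm_times: np.ndarray, t_end: float, tau: float
) -> float:
    """Exact probability that a uniform window [s, s+tau] hits an alarm.

    The window start is uniform on [0, t_end - tau]; the hit set is the
    union of the intervals [a - tau, a] clipped to the start range, so
    the probability is the measure of that union over the range length.
    Serves as the closed-form check for the bootstrap estimator.
    """
    span = t_end - tau
    if span < 0:
        raise ValueError("recording shorter than the window")
    if span == 0:
        return float(len(alarm_times) > 0)
    segs = []
    for a in np.sort(np.asarray(alarm_times, dtype=float)):
        lo, hi = max(a - tau, 0.0), min(a, span)
        if hi >= lo:
            segs.append((lo, hi))
    total = 0.0
    cur_lo, cur_hi = None, None
    for lo, hi in segs:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total / span


# ---------------------------------------------------------------------------
# replicate-derived metrics and WDR

def bootstrap_derived_metrics(
    sensitivity: SensitivityResult, boot: BootstrapEstimate
) -> dict[str, dict[str, float]]:
    """Replicate-level FPR, PPV, NPV, ACC and F1 with means and stds.

    For each window index j a confusion matrix is assembled from the
    fixed case outcomes (N_predicted_events of N_events) and the j-th
    control column (per_window_counts[j] false positives among N
    controls); each metric is computed per replicate and summarised
    across the M replicates.  Replicates where a metric's denominator is
    zero are skipped for that metric, with the skip count reported.
    """
    tp = float(sensitivity.N_predicted_events)
    fn = float(sensitivity.N_events - sensitivity.N_predicted_events)
    n_ctrl = boot.n_controls
    fp = boot.per_window_counts.astype(float)
    tn = n_ctrl - fp
    total = tp + fn + n_ctrl

    raw = {
        "FPR": np.where(n_ctrl > 0, fp / max(n_ctrl, 1), np.nan),
        "PPV": np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), np.nan),
        "NPV": np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1e-300), np.nan),
        "ACC": np.where(total > 0, (tp + tn) / max(total, 1), np.nan),
        "F1": np.where(
            2 * tp + fp + fn > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1e-300), np.nan
        ),
    }
    panel: dict[str, dict[str, float]] = {}
    for name, vals in raw.items():
        ok = ~np.isnan(vals)
        n_ok = int(ok.sum())
        if n_ok == 0:
            panel[name] = {"mean": math.nan, "std": math.nan, "n_skipped": boot.M}
            continue
        mean = float(vals[ok].mean())
        std = float(vals[ok].std(ddof=1)) if n_ok > 1 else 0.0
        panel[name] = {"mean": mean, "std": std, "n_skipped": boot.M - n_ok}
    return panel


@dataclass(frozen=True)
class WDRResult:
    """Work-up to detection ratio with bootstrap-composed uncertainty."""

    mean: float
    std: float
    N_case_predicted: int
    mu_FP: float


def wdr(n_case_predicted: int, boot: BootstrapEstimate) -> WDRResult:
    """WDR = (N_case + mu_FP) / N_case with a composed standard deviation.

    ``mu_i`` is control i's mean window hit over the M replicates and
    ``sigma_i`` its standard deviation; then
    mean = 1 + sum(mu_i)/N_case and std = sqrt(sum(sigma_i^2))/N_case.
    Undefined (flagged NaN) when no case was predicted.
    """
    if n_case_predicted < 1:
        return WDRResult(mean=math.nan, std=math.nan, N_case_predicted=0, mu_FP=math.nan)
    mu_i = boot.hits.mean(axis=1)
    if boot.M > 1:
        sigma_i = boot.hits.std(axis=1, ddof=1)
    else:
        sigma_i = np.zeros(boot.n_controls)
    mu_fp = float(mu_i.sum())
    return WDRResult(
        mean=1.0 + mu_fp / n_case_predicted,
        std=float(np.sqrt((sigma_i**2).sum())) / n_case_predicted,
        N_case_predicted=n_case_predicted,
        mu_FP=mu_fp,
    )


# ---------------------------------------------------------------------------
# alarm burden

@dataclass(frozen=True)
class BurdenSummary:
    """Per-patient alarm-burden metrics.

    r is alarms per hour over the recording; rho the proportion of score
    samples that alarm; r0 and rho0 the false-alarm counterparts.  For a
    case patient the false-alarm rate denominator is T - tau, since no
    false alarm can occur inside the prediction horizon; r0 is flagged
    NaN when the recording is not longer than tau.
    """

    patient_id: str
    group: str
    r: float
    rho: float
    r0: float
    rho0: float
    N_alarms: int
    N_false: int
    N_scores: int
    T_recording: float


def alarm_burden(
    record: PatientRecord,
    series: ScoreSeries,
    alarm_set: AlarmSet,
    config: EvalConfig,
) -> BurdenSummary:
    """Alarm rates and proportions for one patient.

    For cases, false alarms are the early, late and post-event classes;
    for controls every alarm is false.  With tau = tau0 = 0 every
    pre-event alarm is false, so r0 = r and rho0 = rho.
    """
    n_alarms = len(alarm_set)
    n_scores = len(series)
    t_rec = record.t_end
    r = n_alarms / t_rec if t_rec > 0 else math.nan
    rho = n_alarms / n_scores if n_scores > 0 else math.nan
    n_false = alarm_set.n_false
    if record.group == "case":
        tau = config.resolve_tau(record)
        denom = t_rec - tau
        r0 = n_false / denom if denom > 0 else math.nan
    else:
        r0 = n_false / t_rec if t_rec > 0 else math.nan
    rho0 = n_false / n_scores if n_scores > 0 else math.nan
    return BurdenSummary(
        patient_id=record.patient_id,
        group=record.group,
        r=r,
        rho=rho,
        r0=r0,
        rho0=rho0,
        N_alarms=n_alarms,
        N_false=n_false,
        N_scores=n_scores,
        T_recording=t_rec,
    )


def burden_table(summaries: Sequence[BurdenSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


# ---------------------------------------------------------------------------
# alarm time profiles

@dataclass(frozen=True)
class TimeProfile:
    """Pooled alarm counts over temporal classes, normalised.

    ``normalization`` is ``"per_alarm"`` (the three alarm classes are
    divided by the total pre-event alarm count and sum to 1) or
    ``"per_event"`` (all entries divided by the number of events).  In
    both, ``missed_events`` — cases with no on-time alarm — is
    normalised by the number of events.
    """

    counts: dict[str, int]
    normalization: str
    values: dict[str, float]
    N_events: int
    N_alarms: int


def time_profiles(case_alarm_sets: Sequence[AlarmSet]) -> tuple[TimeProfile, TimeProfile]:
    """Per-alarm and per-event time profiles pooled over case patients."""
    sets = [a for a in case_alarm_sets if a.group == "case"]
    if not sets:
        raise ValueError("time profiles require at least one case patient")
    counts = {
        cls: sum(a.count(cls) for a in sets) for cls in ("early", "on_time", "late")
    }
    counts["missed_events"] = sum(a.n_on_time == 0 for a in sets)
    n_events = len(sets)
    n_alarms = counts["early"] + counts["on_time"] + counts["late"]

    per_alarm_vals = {
        cls: counts[cls] / n_alarms if n_alarms else math.nan
        for cls in ("early", "on_time", "late")
    }
    per_alarm_vals["missed_events"] = counts["missed_events"] / n_events
    per_event_vals = {cls: counts[cls] / n_events for cls in counts}

    per_alarm = TimeProfile(
        counts=dict(counts),
        normalization="per_alarm",
        values=per_alarm_vals,
        N_events=n_events,
        N_alarms=n_alarms,
    )
    per_event = TimeProfile(
        counts=dict(counts),
        normalization="per_event",
        values=per_event_vals,
        N_events=n_events,
        N_alarms=n_alarms,
    )
    return per_alarm, per_event
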