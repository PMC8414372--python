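"""Full-pipeline evaluation reports and small ratio utilities.

``evaluate_cohort`` runs the complete evaluation of one score variant on
one cohort — patient-level confusion and threshold sweep, event-level
sensitivity, bootstrapped control-side metrics, WDR, per-patient burden
and pooled time profiles — and returns a JSON-serialisable report that
echoes the fully resolved configuration.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from mewskit.alarms import EvalConfig, alarm_sets_for_cohort
from mewskit.cohort import Cohort, screen_scoreable
from mewskit.event_level import (
    alarm_burden,
    bootstrap_derived_metrics,
    bootstrap_fpr,
    time_dependent_sensitivity,
    time_profiles,
    wdr,
)
from mewskit.patient_level import metrics_from_confusion, patient_confusion, roc_prc_sweep
from mewskit.scoring import ScoreSeries, score_cohort

__all__ = ["relative_change", "percent_change", "evaluate_cohort"]


def relative_change(baseline: float, new: float) -> float:
    """Signed relative change (new - baseline) / baseline.

    Negative for an improvement in a smaller-is-better quantity (e.g. a
    false-positive ratio falling from 0.77 to 0.30 is about -0.61).
    """
    if baseline == 0:
        return math.nan
    return (new - baseline) / baseline


def percent_change(baseline: float, new: float) -> float:
    """Relative change expressed in percent."""
    return 100.0 * relative_change(baseline, new)


def _clean(obj):
    """Make numpy scalars/arrays JSON-friendly."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def evaluate_cohort(
    cohort: Cohort,
    config: EvalConfig,
    series_map: Mapping[str, ScoreSeries] | None = None,
    variance: str = "proportion",
) -> dict:
    """Run the full patient- and event-level evaluation of a cohort.

    When ``series_map`` is omitted the cohort is screened for scoreable
    records and scored with the variant named in ``config``.  With
    ``config.tau = None`` (horizon spanning the whole pre-event stay)
    the event-level sensitivity coincides with the patient-level TPR;
    with ``tau = 0`` the sensitivity block is skipped and every alarm
    counts as false in the burden metrics.
    """
    exclusions: dict[str, str] = {}
    if series_map is None:
        cohort, exclusions = screen_scoreable(cohort)
        series_map = score_cohort(
            cohort, variant=config.variant, t_mews=config.t_mews
        )
    series_map = dict(series_map)

    report: dict = {
        "config": config.to_dict(),
        "n_cases": len(cohort.cases),
        "n_controls": len(cohort.controls),
        "exclusions": {"unscoreable": exclusions},
    }

    # patient level
    counts = patient_confusion(cohort, series_map, config.k)
    panel = metrics_from_confusion(counts)
    report["patient_level"] = {
        "confusion": {"TP": counts.TP, "FP": counts.FP, "FN": counts.FN, "TN": counts.TN},
        "metrics": panel.to_dict(),
    }
    if cohort.cases and cohort.controls:
        sweep = roc_prc_sweep(cohort, series_map)
        report["sweep"] = {
            "per_threshold": sweep.to_frame().to_dict(orient="records"),
            "AUROC": sweep.auroc,
            "AUPRC": sweep.auprc,
        }

    # event level
    alarm_sets = alarm_sets_for_cohort(cohort, series_map, config)
    event: dict = {}
    tau_is_zero = config.tau is not None and config.tau == 0
    sens = None
    if cohort.cases and not tau_is_zero:
        sens = time_dependent_sensitivity(cohort.cases, series_map, config)
        event["sensitivity"] = {
            "S": sens.S,
            "N_predicted_events": sens.N_predicted_events,
            "N_events": sens.N_events,
            "excluded_short_stay": list(sens.excluded),
        }
    if cohort.controls:
        boot = bootstrap_fpr(cohort.controls, series_map, config, variance=variance)
        event["bootstrap_fpr"] = {
            "mean": boot.mean,
            "std": boot.std,
            "M": boot.M,
            "n_controls": boot.n_controls,
            "mu_FP": boot.mu_FP,
            "excluded_short_recording": list(boot.excluded),
        }
        if sens is not None:
            event["derived_metrics"] = bootstrap_derived_metrics(sens, boot)
            w = wdr(sens.N_predicted_events, boot)
            event["WDR"] = {
                "mean": w.mean,
                "std": w.std,
                "N_case_predicted": w.N_case_predicted,
                "mu_FP": w.mu_FP,
            }

    burdens = [
        alarm_burden(rec, series_map[rec.patient_id], alarm_sets[rec.patient_id], config)
        for rec in cohort
    ]
    by_group: dict = {}
    for grp in ("case", "control"):
        rows = [b for b in burdens if b.group == grp]
        if rows:
            entry = {}
            for name in ("r", "rho", "r0", "rho0"):
                vals = [v for b in rows if not math.isnan(v := getattr(b, name))]
                entry[name] = float(np.mean(vals)) if vals else math.nan
            entry["n_patients"] = len(rows)
            by_group[grp] = entry
    event["burden"] = by_group

    case_sets = [alarm_sets[r.patient_id] for r in cohort.cases]
    if case_sets:
        per_alarm, per_event = time_profiles(case_sets)
        event["time_profiles"] = {
            "counts": per_alarm.counts,
            "per_alarm": per_alarm.values,
            "per_event": per_event.values,
            "N_events": per_alarm.N_events,
        }

    report["event_level"] = event
    return _clean(report)
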