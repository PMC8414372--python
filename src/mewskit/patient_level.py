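"""Patient-level evaluation: any-crossing confusion matrix and sweeps.

A case patient counts as one true positive if the score ever exceeded
the threshold during the stay — regardless of how many times — and as a
false negative otherwise; a control counts as one false positive if the
score ever exceeded the threshold and as a true negative otherwise.
Scalar metrics and ROC / precision-recall sweeps over all 14 discrete
thresholds (k = 0..13) are derived from these per-patient outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mewskit.cohort import Cohort
from mewskit.scoring import ScoreSeries

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "patient_confusion",
    "metrics_from_confusion",
    "roc_prc_sweep",
    "SweepResult",
]

#: Threshold sweep: the score is an integer in [0, 14], so k = 13 is the
#: largest threshold that any sample can strictly exceed.
THRESHOLDS = tuple(range(14))


@dataclass(frozen=True)
class ConfusionCounts:
    """Patient-level confusion matrix (patients, not alarms)."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.TP + self.FN

    @property
    def n_controls(self) -> int:
        return self.FP + self.TN

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


def _ratio(num: float, den: float) -> float:
    """Plain ratio with NaN (flagged undefined) on a zero denominator."""
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class MetricPanel:
    """Scalar classification metrics; NaN flags an undefined ratio."""

    TPR: float
    FPR: float
    PPV: float
    NPV: float
    ACC: float
    F1: float
    WDR: float

    def to_dict(self) -> dict[str, float]:
        return {
            "TPR": self.TPR,
            "FPR": self.FPR,
            "PPV": self.PPV,
            "NPV": self.NPV,
            "ACC": self.ACC,
            "F1": self.F1,
            "WDR": self.WDR,
        }


def patient_confusion(
    cohort: Cohort, series_map: dict[str, ScoreSeries], k: int
) -> ConfusionCounts:
    """Any-crossing confusion counts at threshold k.

    A patient alarms if any score total in the stay strictly exceeds k.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    tp = fp = fn = tn = 0
    for rec in cohort:
        alarmed = bool(np.any(series_map[rec.patient_id].totals > k))
        if rec.group == "case":
            tp += alarmed
            fn += not alarmed
        else:
            fp += alarmed
            tn += not alarmed
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def metrics_from_confusion(counts: ConfusionCounts) -> MetricPanel:
    """Scalar metrics from a confusion matrix.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), ACC = (TP+TN)/total, F1 = harmonic mean of PPV
    and TPR, and WDR = (TP+FP)/TP — the work-up to detection ratio, the
    number of patients worked up per detected event.  Zero denominators
    yield NaN rather than an exception so threshold sweeps never abort.
    """
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    tpr = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    return MetricPanel(
        TPR=tpr,
        FPR=_ratio(fp, fp + tn),
        PPV=ppv,
        NPV=_ratio(tn, tn + fn),
        ACC=_ratio(tp + tn, counts.total),
        F1=f1,
        WDR=_ratio(tp + fp, tp),
    )


@dataclass
class SweepResult:
    """Per-threshold metrics plus areas under the ROC and PR curves."""

    thresholds: tuple[int, ...]
    confusions: list[ConfusionCounts]
    panels: list[MetricPanel]
    auroc: float
    auprc: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, c, p in zip(self.thresholds, self.confusions, self.panels):
            row = {"k": k, "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN}
            row.update(p.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict[str, float]:
        return {"AUROC": self.auroc, "AUPRC": self.auprc}


def _trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def roc_prc_sweep(cohort: Cohort, series_map: dict[str, ScoreSeries]) -> SweepResult:
    """Evaluate all 14 discrete thresholds and integrate ROC / PR curves.

    ROC points (FPR, TPR) at each k are augmented with the anchors
    (0, 0) and (1, 1) — the degenerate thresholds above and below the
    score range — and integrated by the trapezoid rule.  Because the
    score is a 15-level integer, this ROC is complete and its area
    equals the rank concordance (ties counted half) of the per-patient
    maximum score.  The PR curve uses the same operating points with a
    (recall = 0, precision = 1) anchor.
    """
    n_cases = len(cohort.cases)
    n_controls = len(cohort.controls)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("sweep requires at least one case and one control")

    confusions = [patient_confusion(cohort, series_map, k) for k in THRESHOLDS]
    panels = [metrics_from_confusion(c) for c in confusions]

    fpr = np.array([0.0] + [p.FPR for p in panels] + [1.0])
    tpr = np.array([0.0] + [p.TPR for p in panels] + [1.0])
    auroc = _trapezoid_auc(fpr, tpr)

    recall = np.array([p.TPR for p in panels])
    precision = np.array([p.PPV for p in panels])
    # undefined precision (no alarms at all at this k) contributes no point
    ok = ~np.isnan(precision)
    recall = np.concatenate([[0.0], recall[ok]])
    precision = np.concatenate([[1.0], precision[ok]])
    auprc = _trapezoid_auc(recall, precision)

    return SweepResult(
        thresholds=THRESHOLDS,
        confusions=confusions,
        panels=panels,
        auroc=auroc,
        auprc=auprc,
    )


def max_score_concordance(cohort: Cohort, series_map: dict[str, ScoreSeries]) -> float:
    """Rank concordance of the per-patient maximum score (ties = 0.5).

    Exhaustive pairwise comparison of case vs control maxima; equals the
    trapezoid AUROC of the complete discrete ROC.  Quadratic in cohort
    size — intended as an independent cross-check on small cohorts.
    """
    case_max = [series_map[r.patient_id].totals.max(initial=0) for r in cohort.cases]
    ctrl_max = [series_map[r.patient_id].totals.max(initial=0) for r in cohort.controls]
    wins = 0.0
    for a in case_max:
        for b in ctrl_max:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(case_max) * len(ctrl_max))
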