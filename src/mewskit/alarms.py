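"""Threshold alarms and their temporal classification.

An alarm is an instantaneous notification raised whenever the score
strictly exceeds a threshold k; there is no grouping or lockout.  For a
case patient, alarms are classified against a *prediction horizon*
[t_min, t_max] and a *lead time* [t_max, t_event], where
t_max = t_event - tau0 and t_min = t_max - tau:

* ``early``      — before t_min: too far ahead of the event to act on;
* ``on_time``    — within [t_min, t_max]: actionable true alarms;
* ``late``       — in (t_max, t_event): insufficient intervention time;
* ``post_event`` — at or after the event.

Early, late and post-event alarms are all false alarms.  Every alarm on
a control patient is a false alarm (``control_false``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from mewskit.cohort import PatientRecord
from mewskit.scoring import ScoreSeries

__all__ = ["EvalConfig", "AlarmSet", "generate_alarms", "classify_alarms"]

ALARM_CLASSES = ("early", "on_time", "late", "post_event", "control_false")

FALSE_CLASSES = ("early", "late", "post_event", "control_false")


@dataclass(frozen=True)
class EvalConfig:
    """All evaluation parameters in one place.

    Attributes
    ----------
    k : int
        Alarm threshold; an alarm fires where the score total > k.
        Swept over 0..13 (14 is the maximum achievable total).
    tau : float or None
        Prediction-horizon length in hours.  ``None`` means "the whole
        pre-event stay" (per-record tau = t_event), the limit in which
        event-level sensitivity coincides with patient-level TPR.
    tau0 : float
        Lead time in hours reserved for intervention.
    t_mews : float or None
        Interval length for the regular-grid score variants; ``None``
        for the irregular base variant.
    statistic : {"median", "worst"} or None
        Interval summary statistic; ``None`` for the base variant.
    M : int
        Number of bootstrap windows per control patient.
    seed : int
        RNG seed for all stochastic steps.
    """

    k: int = 4
    tau: float | None = 12.0
    tau0: float = 0.0
    t_mews: float | None = None
    statistic: Literal["median", "worst"] | None = None
    M: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.k <= 13:
            raise ValueError(f"k must be in [0, 13], got {self.k}")
        if self.tau is not None and self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.tau0 < 0:
            raise ValueError(f"tau0 must be >= 0, got {self.tau0}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if (self.statistic is None) != (self.t_mews is None):
            raise ValueError("t_mews and statistic must be given together")

    @property
    def variant(self) -> str:
        return "base" if self.statistic is None else self.statistic

    def resolve_tau(self, record: PatientRecord) -> float:
        """Horizon length for one record (full stay when tau is None)."""
        return record.t_end if self.tau is None else self.tau

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "tau": self.tau,
            "tau0": self.tau0,
            "t_mews": self.t_mews,
            "statistic": self.statistic,
            "M": self.M,
            "seed": self.seed,
        }


@dataclass
class AlarmSet:
    """Alarm timestamps of one patient with temporal class labels.

    ``window`` is (t_min, t_max, t_event) for case patients and ``None``
    for controls.  ``evaluable`` is False when tau + tau0 exceeds the
    case's pre-event stay, i.e. the horizon does not fit the recording.
    """

    patient_id: str
    group: str
    times: np.ndarray
    classes: np.ndarray  # same length, values from ALARM_CLASSES
    window: tuple[float, float, float] | None = None
    evaluable: bool = True

    def __len__(self) -> int:
        return len(self.times)

    def count(self, cls: str) -> int:
        if cls not in ALARM_CLASSES:
            raise ValueError(f"unknown alarm class {cls!r}")
        return int(np.sum(self.classes == cls))

    @property
    def n_false(self) -> int:
        return int(np.isin(self.classes, FALSE_CLASSES).sum())

    @property
    def n_on_time(self) -> int:
        return self.count("on_time")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_id, "time_h": self.times, "class": self.classes}
        )


def generate_alarms(series: ScoreSeries, k: int) -> np.ndarray:
    """Alarm times: every score time where the total strictly exceeds k."""
    return series.times[series.totals > k]


def classify_alarms(
    alarms: np.ndarray, record: PatientRecord, config: EvalConfig
) -> AlarmSet:
    """Label each alarm of one patient by its temporal class.

    For controls every alarm is ``control_false``.  For cases the
    on-time window is the closed interval [t_min, t_max]; ``late`` is
    the half-open (t_max, t_event) and ``post_event`` is t >= t_event.
    A case whose stay is shorter than tau + tau0 is still classified
    but marked not evaluable (the horizon window does not fit).
    """
    alarms = np.asarray(alarms, dtype=float)
    if record.group == "control":
        return AlarmSet(
            patient_id=record.patient_id,
            group="control",
            times=alarms,
            classes=np.full(len(alarms), "control_false", dtype=object),
        )

    t_event = record.t_end
    tau = config.resolve_tau(record)
    t_max = t_event - config.tau0
    t_min = t_max - tau
    classes = np.empty(len(alarms), dtype=object)
    classes[alarms < t_min] = "early"
    classes[(alarms >= t_min) & (alarms <= t_max)] = "on_time"
    classes[(alarms > t_max) & (alarms < t_event)] = "late"
    classes[alarms >= t_event] = "post_event"
    return AlarmSet(
        patient_id=record.patient_id,
        group="case",
        times=alarms,
        classes=classes,
        window=(t_min, t_max, t_event),
        evaluable=tau + config.tau0 <= t_event,
    )


def alarm_sets_for_cohort(
    cohort, series_map: dict[str, ScoreSeries], config: EvalConfig
) -> dict[str, AlarmSet]:
    """Generate and classify alarms for every patient in a cohort."""
    out = {}
    for rec in cohort:
        s = series_map[rec.patient_id]
        out[rec.patient_id] = classify_alarms(generate_alarms(s, config.k), rec, config)
    return out
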