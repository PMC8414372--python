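"""Cohort data model and long-format CSV I/O.

A cohort is a collection of patient records.  Each record carries
irregularly sampled measurements of up to five physiological parameters
(systolic blood pressure, heart rate, respiratory rate, temperature and
Glasgow Coma Score), a case/control label and the recording end time.
For case patients the recording ends at the first code-blue event, so
``t_end`` doubles as the event time; for controls it is the discharge
time.  All times are continuous hours since ICU admission (t = 0).

The on-disk format is a long CSV with one row per measurement and the
columns ``patient_id, group, parameter, time_h, value, t_end_h``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Recognised physiological parameters.
PARAMETERS = ("SBP", "HR", "RR", "TEMP", "GCS")

#: Parameters that must each have at least one measurement for a record to
#: be scoreable.  GCS (consciousness) is optional: when it was never
#: recorded the consciousness term is simply omitted from the score.
MANDATORY = ("SBP", "HR", "RR", "TEMP")

#: Plausibility bounds per parameter, in physical units (mmHg, bpm,
#: breaths/min, degrees C, GCS points).  Configurable via ``read_cohort``.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "SBP": (20.0, 300.0),
    "HR": (0.0, 300.0),
    "RR": (0.0, 80.0),
    "TEMP": (25.0, 45.0),
    "GCS": (3.0, 15.0),
}

CSV_COLUMNS = ["patient_id", "group", "parameter", "time_h", "value", "t_end_h"]


class CohortFormatError(ValueError):
    """Raised when an input file does not conform to the cohort schema."""


@dataclass(frozen=True)
class VitalSample:
    """One timestamped measurement of one physiological parameter."""

    parameter: str
    time: float  # hours since admission
    value: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.time < 0:
            raise ValueError(f"negative sample time {self.time}")


@dataclass
class PatientRecord:
    """One patient's irregular multivariate vital-sign record.

    ``samples`` maps parameter name to two parallel float arrays
    ``(times, values)`` sorted by time.  For case patients ``t_end`` is
    the time of the first code-blue event (data are truncated there); for
    controls it is the discharge time.
    """

    patient_id: str
    group: str  # "case" | "control"
    t_end: float
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if not np.isfinite(self.t_end) or self.t_end < 0:
            raise ValueError(f"invalid t_end {self.t_end}")
        for param, (t, v) in self.samples.items():
            if len(t) != len(v):
                raise ValueError(f"{param}: times and values differ in length")
            if len(t) and t.max() > self.t_end + 1e-9:
                raise ValueError(
                    f"{self.patient_id}/{param}: sample after recording end"
                )

    @property
    def t_event(self) -> float | None:
        """Event time for case patients, ``None`` for controls."""
        return self.t_end if self.group == "case" else None

    def times(self, parameter: str) -> np.ndarray:
        return self.samples.get(parameter, (np.empty(0), np.empty(0)))[0]

    def values(self, parameter: str) -> np.ndarray:
        return self.samples.get(parameter, (np.empty(0), np.empty(0)))[1]

    def n_samples(self, parameter: str) -> int:
        return len(self.times(parameter))

    def missing_mandatory(self) -> list[str]:
        """Mandatory parameters with no measurement at all."""
        return [p for p in MANDATORY if self.n_samples(p) == 0]

    def is_scoreable(self) -> bool:
        return not self.missing_mandatory()


@dataclass
class Cohort:
    """A collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    @property
    def cases(self) -> list[PatientRecord]:
        return [r for r in self.records if r.group == "case"]

    @property
    def controls(self) -> list[PatientRecord]:
        return [r for r in self.records if r.group == "control"]


def _record_from_rows(pid: str, rows: pd.DataFrame, duplicates: str) -> PatientRecord:
    groups = rows["group"].unique()
    if len(groups) > 1:
        raise CohortFormatError(f"{pid}: conflicting group labels {sorted(groups)}")
    t_ends = rows["t_end_h"].unique()
    if len(t_ends) > 1:
        raise CohortFormatError(f"{pid}: conflicting t_end_h values")
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for param, sub in rows.groupby("parameter", sort=False):
        # stable sort keeps input order for equal timestamps
        sub = sub.sort_values("time_h", kind="stable")
        if sub["time_h"].duplicated().any():
            if duplicates == "error":
                raise CohortFormatError(f"{pid}/{param}: duplicate timestamps")
            n_dup = int(sub["time_h"].duplicated().sum())
            log.warning("%s/%s: %d duplicate timestamps, keeping last", pid, param, n_dup)
            sub = sub[~sub["time_h"].duplicated(keep="last")]
        samples[str(param)] = (
            sub["time_h"].to_numpy(dtype=float),
            sub["value"].to_numpy(dtype=float),
        )
    return PatientRecord(
        patient_id=pid, group=str(groups[0]), t_end=float(t_ends[0]), samples=samples
    )


def validate_rows(
    df: pd.DataFrame, bounds: Mapping[str, tuple[float, float]] | None = None
) -> pd.Series:
    """Return a boolean mask of rows violating plausibility bounds.

    GCS must additionally be integer-valued.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    bad = pd.Series(False, index=df.index)
    for param, (lo, hi) in bounds.items():
        sel = df["parameter"] == param
        v = df.loc[sel, "value"]
        invalid = (v < lo) | (v > hi) | ~np.isfinite(v)
        if param == "GCS":
            invalid |= v != np.round(v)
        bad.loc[sel] = invalid
    bad |= ~df["parameter"].isin(PARAMETERS)
    bad |= df["time_h"] < 0
    return bad


def read_cohort(
    path: str | Path,
    validation: str = "error",
    bounds: Mapping[str, tuple[float, float]] | None = None,
    duplicates: str = "keep-last",
) -> Cohort:
    """Read a long-format vital-sign CSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV with columns ``patient_id, group, parameter, time_h, value,
        t_end_h`` (comma-separated, UTF-8, '.' decimal, header required).
    validation
        ``"error"`` raises on the first out-of-bounds row, naming it;
        ``"drop"`` silently removes offending rows.
    bounds
        Plausibility bounds, defaulting to :data:`DEFAULT_BOUNDS`.
    duplicates
        Policy for repeated (patient, parameter, time) rows:
        ``"keep-last"`` (EHR correction semantics) or ``"error"``.
    """
    if validation not in ("error", "drop"):
        raise ValueError(f"unknown validation policy {validation!r}")
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing columns: {missing}")
    if df["t_end_h"].isna().any():
        bad_ids = sorted(df.loc[df["t_end_h"].isna(), "patient_id"].unique())
        raise CohortFormatError(f"records with no t_end_h: {bad_ids}")

    bad = validate_rows(df, bounds)
    if bad.any():
        if validation == "error":
            i = int(bad.idxmax())
            row = df.loc[i]
            raise CohortFormatError(
                f"row {i}: {row['parameter']}={row['value']} at t={row['time_h']} "
                f"for patient {row['patient_id']} violates validation bounds"
            )
        df = df[~bad]

    records = [
        _record_from_rows(str(pid), rows, duplicates)
        for pid, rows in df.groupby("patient_id", sort=False)
    ]
    return Cohort(records=records, metadata={"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to long-format CSV; inverse of :func:`read_cohort`."""
    frames = []
    for rec in cohort:
        for param in PARAMETERS:
            t = rec.times(param)
            if len(t) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": rec.patient_id,
                        "group": rec.group,
                        "parameter": param,
                        "time_h": t,
                        "value": rec.values(param),
                        "t_end_h": rec.t_end,
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=CSV_COLUMNS)
    out.to_csv(path, index=False)


def screen_scoreable(cohort: Cohort) -> tuple[Cohort, dict[str, str]]:
    """Split a cohort into scoreable records and an exclusion report.

    A record is scoreable when every mandatory vital sign (SBP, HR, RR,
    TEMP) has at least one measurement; a record missing only GCS is
    retained.  Returns the retained cohort and a map
    ``patient_id -> reason`` for the exclusions.  Idempotent.
    """
    kept: list[PatientRecord] = []
    excluded: dict[str, str] = {}
    for rec in cohort:
        missing = rec.missing_mandatory()
        if missing:
            excluded[rec.patient_id] = "no " + "/".join(missing) + " measurements"
        else:
            kept.append(rec)
    meta = dict(cohort.metadata)
    meta["n_excluded_unscoreable"] = len(excluded)
    return Cohort(records=kept, metadata=meta), excluded


def write_exclusion_report(report: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def cohorts_equal(a: Cohort, b: Cohort, rtol: float = 0.0, atol: float = 1e-9) -> bool:
    """Structural equality of two cohorts (ids, labels, times, values)."""
    if len(a) != len(b):
        return False
    b_by_id = {r.patient_id: r for r in b}
    for ra in a:
        rb = b_by_id.get(ra.patient_id)
        if rb is None or ra.group != rb.group:
            return False
        if not np.isclose(ra.t_end, rb.t_end, rtol=rtol, atol=atol):
            return False
        params = {p for p in PARAMETERS if ra.n_samples(p) or rb.n_samples(p)}
        for p in params:
            ta, va, tb, vb = ra.times(p), ra.values(p), rb.times(p), rb.values(p)
            if len(ta) != len(tb):
                return False
            if not (
                np.allclose(ta, tb, rtol=rtol, atol=atol)
                and np.allclose(va, vb, rtol=rtol, atol=atol)
            ):
                return False
    return True
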