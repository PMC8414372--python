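"""MEWS scoring engine.

The Modified Early Warning Score (MEWS) assigns 0-3 points to each of
five physiological parameters — systolic blood pressure (SBP), heart
rate (HR), respiratory rate (RR), temperature (TEMP) and consciousness
level (AVPU, derived here from the Glasgow Coma Score) — and sums them.
With the default table the maximum total is 14 (3+3+3+2+3).

Three score-series variants are produced from an irregular record:

* ``mews_base`` — a new score every time any parameter is refreshed,
  carrying each parameter forward until its next measurement (LOCF).
* ``mews_interval`` with the *median* statistic — scores on a regular
  grid of length ``t_mews``, each parameter summarised by the element
  median of its in-interval measurements.
* ``mews_interval`` with the *worst* statistic — same grid, each
  parameter summarised by the measurement that maximises its points.

Empty intervals fall back to the last recorded value (flagged imputed).

Band boundaries
---------------
The published point table leaves gaps between printed integer bands
(e.g. SBP 70-71).  Bands here are made contiguous by treating the
lower-severity band as half-open at its shared edge, so every real value
maps to exactly one point value; the table is data, not code, so
alternative conventions or other early-warning scores can be configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from mewskit.cohort import MANDATORY, PARAMETERS, PatientRecord

__all__ = [
    "Band",
    "ScoringTable",
    "DEFAULT_TABLE",
    "ScoreSeries",
    "map_gcs_to_avpu",
    "subscore",
    "compute_mews",
    "mews_base",
    "mews_interval",
]


@dataclass(frozen=True)
class Band:
    """One contiguous value band mapped to a point value.

    ``lo``/``hi`` may be ``-inf``/``+inf``; ``lo_closed``/``hi_closed``
    state whether the corresponding edge belongs to the band.
    """

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool
    points: int

    def contains(self, value: np.ndarray | float) -> np.ndarray | bool:
        above = value >= self.lo if self.lo_closed else value > self.lo
        below = value <= self.hi if self.hi_closed else value < self.hi
        return above & below if isinstance(value, np.ndarray) else (above and below)


@dataclass(frozen=True)
class ScoringTable:
    """Per-parameter point-assignment bands.

    ``bands`` maps parameter name to an ordered band list that must tile
    the real line without overlap (checked on construction).
    """

    bands: Mapping[str, Sequence[Band]]

    def __post_init__(self) -> None:
        for param, bl in self.bands.items():
            prev = None
            for b in bl:
                if b.lo > b.hi:
                    raise ValueError(f"{param}: band with lo > hi")
                if prev is not None:
                    if b.lo != prev.hi or b.lo_closed == prev.hi_closed:
                        raise ValueError(f"{param}: bands not contiguous at {b.lo}")
                prev = b
            if bl and (bl[0].lo != -math.inf or bl[-1].hi != math.inf):
                raise ValueError(f"{param}: bands do not cover the real line")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def max_points(self, parameter: str) -> int:
        return max(b.points for b in self.bands[parameter])

    def max_total(self, include: Iterable[str] | None = None) -> int:
        params = self.parameters if include is None else tuple(include)
        return sum(self.max_points(p) for p in params)

    def score(self, parameter: str, values: np.ndarray | float) -> np.ndarray | int:
        """Points for one or many values of a parameter."""
        if parameter not in self.bands:
            raise KeyError(f"no bands for parameter {parameter!r}")
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{parameter}: non-finite value")
        out = np.full(arr.shape, -1, dtype=int)
        for b in self.bands[parameter]:
            out[b.contains(arr)] = b.points
        if np.any(out < 0):  # unreachable with a tiling table
            raise ValueError(f"{parameter}: value outside all bands")
        return out if isinstance(values, np.ndarray) else int(out)

    def to_dict(self) -> dict:
        return {
            p: [
                {
                    "lo": None if b.lo == -math.inf else b.lo,
                    "hi": None if b.hi == math.inf else b.hi,
                    "lo_closed": b.lo_closed,
                    "hi_closed": b.hi_closed,
                    "points": b.points,
                }
                for b in bl
            ]
            for p, bl in self.bands.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringTable":
        bands = {
            p: [
                Band(
                    lo=-math.inf if e["lo"] is None else float(e["lo"]),
                    hi=math.inf if e["hi"] is None else float(e["hi"]),
                    lo_closed=bool(e["lo_closed"]),
                    hi_closed=bool(e["hi_closed"]),
                    points=int(e["points"]),
                )
                for e in bl
            ]
            for p, bl in d.items()
        }
        return cls(bands=bands)


def _bands(*rows: tuple[float, float, bool, bool, int]) -> list[Band]:
    return [Band(*r) for r in rows]


inf = math.inf

#: Default MEWS point table.  GCS bands encode the AVPU mapping
#: (Alert = GCS 14-15 -> 0, Voice = 10-13 -> 1, Pain = 4-9 -> 2,
#: Unresponsive = 3 -> 3).
DEFAULT_TABLE = ScoringTable(
    bands={
        "SBP": _bands(
            (-inf, 70, False, True, 3),
            (70, 80, False, True, 2),
            (80, 100, False, True, 1),
            (100, 200, False, False, 0),
            (200, inf, True, False, 2),
        ),
        "HR": _bands(
            (-inf, 40, False, True, 2),
            (40, 50, False, True, 1),
            (50, 100, False, True, 0),
            (100, 110, False, True, 1),
            (110, 130, False, False, 2),
            (130, inf, True, False, 3),
        ),
        "RR": _bands(
            (-inf, 9, False, False, 2),
            (9, 15, True, False, 0),
            (15, 21, True, False, 1),
            (21, 30, True, False, 2),
            (30, inf, True, False, 3),
        ),
        "TEMP": _bands(
            (-inf, 35, False, False, 2),
            (35, 38.5, True, False, 0),
            (38.5, inf, True, False, 2),
        ),
        "GCS": _bands(
            (-inf, 3, False, True, 3),
            (3, 9, False, True, 2),
            (9, 13, False, True, 1),
            (13, inf, False, False, 0),
        ),
    }
)

_AVPU_LEVELS = ("Alert", "Voice", "Pain", "Unresponsive")


def map_gcs_to_avpu(gcs: int) -> str:
    """Map a Glasgow Coma Score to an AVPU consciousness level.

    Alert = GCS 14-15; reacting to Voice = GCS 10-13; reacting to
    Pain = GCS 4-9; Unresponsive = GCS 3.
    """
    if gcs != int(gcs) or not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be an integer in [3, 15], got {gcs}")
    gcs = int(gcs)
    if gcs >= 14:
        return "Alert"
    if gcs >= 10:
        return "Voice"
    if gcs >= 4:
        return "Pain"
    return "Unresponsive"


def subscore(
    parameter: str, value: float, table: ScoringTable = DEFAULT_TABLE
) -> int:
    """Points assigned to a single parameter value."""
    return int(table.score(parameter, float(value)))


def compute_mews(
    values: Mapping[str, float], table: ScoringTable = DEFAULT_TABLE
) -> tuple[int, dict[str, int]]:
    """Total MEWS and per-parameter subscores for one set of values.

    SBP, HR, RR and TEMP are mandatory; GCS is optional and, when
    absent, the consciousness term is omitted from the total.
    """
    missing = [p for p in MANDATORY if p not in values]
    if missing:
        raise ValueError(f"missing mandatory parameters: {missing}")
    subs = {p: subscore(p, v, table) for p, v in values.items() if p in table.bands}
    return sum(subs.values()), subs


@dataclass
class ScoreSeries:
    """Timestamped MEWS totals with subscores and imputation flags.

    ``subscores[param]`` is a float array with NaN where the parameter
    had no current (measured or carried-forward) value;
    ``imputed[param]`` is True where the value was carried forward
    rather than measured in place.
    """

    patient_id: str
    times: np.ndarray
    totals: np.ndarray
    subscores: dict[str, np.ndarray]
    imputed: dict[str, np.ndarray]
    avpu_present: bool
    variant: str = "base"

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("score times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times, "total": self.totals})
        for p in PARAMETERS:
            if p in self.subscores:
                df[f"{p}_points"] = self.subscores[p]
                df[f"{p}_imputed"] = self.imputed[p]
        df.insert(0, "patient_id", self.patient_id)
        return df


def _series_from_values(
    record: PatientRecord,
    times: np.ndarray,
    values: dict[str, np.ndarray],
    imputed: dict[str, np.ndarray],
    table: ScoringTable,
    variant: str,
) -> ScoreSeries:
    """Score per-time parameter values (NaN = unavailable) into a series."""
    subs: dict[str, np.ndarray] = {}
    total = np.zeros(len(times), dtype=int)
    for p, vals in values.items():
        pts = np.full(len(times), np.nan)
        avail = ~np.isnan(vals)
        if avail.any():
            pts[avail] = table.score(p, vals[avail])
        subs[p] = pts
        total = total + np.where(avail, np.nan_to_num(pts), 0.0).astype(int)
    return ScoreSeries(
        patient_id=record.patient_id,
        times=times,
        totals=total,
        subscores=subs,
        imputed=imputed,
        avpu_present=record.n_samples("GCS") > 0,
        variant=variant,
    )


def mews_base(
    record: PatientRecord,
    table: ScoringTable = DEFAULT_TABLE,
    max_carry_h: float = math.inf,
) -> ScoreSeries:
    """Irregular MEWS: one score per distinct measurement time.

    A new total is computed every time any parameter (vitals or GCS) is
    refreshed, with all other parameters carried forward from their last
    measurement.  No score is emitted before every mandatory parameter
    has been observed at least once.  ``max_carry_h`` optionally expires
    carried-forward values older than the given age; an expired
    mandatory parameter suppresses the score at that time, an expired
    GCS drops only the consciousness term.
    """
    if not record.is_scoreable():
        raise ValueError(
            f"{record.patient_id}: unscoreable, missing {record.missing_mandatory()}"
        )
    present = [p for p in PARAMETERS if record.n_samples(p) > 0]
    all_times = np.unique(np.concatenate([record.times(p) for p in present]))

    values: dict[str, np.ndarray] = {}
    imputed: dict[str, np.ndarray] = {}
    available = np.ones(len(all_times), dtype=bool)
    for p in present:
        tp, vp = record.times(p), record.values(p)
        idx = np.searchsorted(tp, all_times, side="right") - 1
        has = idx >= 0
        age = np.where(has, all_times - tp[np.clip(idx, 0, None)], np.inf)
        fresh = has & (age <= max_carry_h)
        vals = np.full(len(all_times), np.nan)
        vals[fresh] = vp[idx[fresh]]
        measured_here = fresh & np.isin(all_times, tp)
        values[p] = vals
        imputed[p] = fresh & ~measured_here
        if p in MANDATORY:
            available &= fresh

    times = all_times[available]
    values = {p: v[available] for p, v in values.items()}
    imputed = {p: f[available] for p, f in imputed.items()}
    return _series_from_values(record, times, values, imputed, table, "base")


def _element_median(values: np.ndarray) -> float:
    """Lower element median: always one of the observed values."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def _worst(values: np.ndarray, times: np.ndarray, param: str, table: ScoringTable) -> float:
    """The in-interval value maximising the point assignment.

    Ties on points are broken by the most recent measurement.
    """
    pts = table.score(param, values)
    top = pts == pts.max()
    return float(values[top][np.argmax(times[top])])


def mews_interval(
    record: PatientRecord,
    t_mews: float,
    statistic: Literal["median", "worst"],
    table: ScoringTable = DEFAULT_TABLE,
    max_carry_h: float = math.inf,
) -> ScoreSeries:
    """Regularly sampled MEWS over intervals of length ``t_mews`` hours.

    The grid is anchored at admission and scores are stamped at interval
    ends t = t_mews, 2*t_mews, ... <= t_end.  Within each interval every
    parameter is summarised by the chosen statistic of its measurements;
    an interval with no new measurement for a parameter falls back to
    the last recorded value (flagged imputed).  As with ``mews_base`` no
    score is emitted before all mandatory parameters have been observed.
    """
    if t_mews <= 0:
        raise ValueError(f"t_mews must be positive, got {t_mews}")
    if statistic not in ("median", "worst"):
        raise ValueError(f"statistic must be 'median' or 'worst', got {statistic!r}")
    if not record.is_scoreable():
        raise ValueError(
            f"{record.patient_id}: unscoreable, missing {record.missing_mandatory()}"
        )

    n_intervals = int(np.floor(record.t_end / t_mews + 1e-9))
    grid = (np.arange(n_intervals) + 1) * t_mews
    present = [p for p in PARAMETERS if record.n_samples(p) > 0]

    values: dict[str, np.ndarray] = {}
    imputed: dict[str, np.ndarray] = {}
    available = np.ones(n_intervals, dtype=bool)
    for p in present:
        tp, vp = record.times(p), record.values(p)
        vals = np.full(n_intervals, np.nan)
        flags = np.zeros(n_intervals, dtype=bool)
        # interval j (1-based) covers ((j-1)T, jT]; t=0 belongs to interval 1
        bin_idx = np.maximum(np.ceil(tp / t_mews - 1e-9).astype(int), 1) - 1
        for j in range(n_intervals):
            sel = bin_idx == j
            t_hi = grid[j]
            if sel.any():
                if statistic == "median":
                    vals[j] = _element_median(vp[sel])
                else:
                    vals[j] = _worst(vp[sel], tp[sel], p, table)
            else:
                prior = tp <= t_hi + 1e-9
                if prior.any():
                    i_last = int(np.flatnonzero(prior)[-1])
                    if t_hi - tp[i_last] <= max_carry_h:
                        vals[j] = vp[i_last]
                        flags[j] = True
        values[p] = vals
        imputed[p] = flags
        if p in MANDATORY:
            available &= ~np.isnan(vals)

    times = grid[available]
    values = {p: v[available] for p, v in values.items()}
    imputed = {p: f[available] for p, f in imputed.items()}
    return _series_from_values(
        record, times, values, imputed, table, f"{statistic}@{t_mews}h"
    )


def score_cohort(
    cohort,
    variant: Literal["base", "median", "worst"] = "base",
    t_mews: float | None = None,
    table: ScoringTable = DEFAULT_TABLE,
    max_carry_h: float = math.inf,
) -> dict[str, ScoreSeries]:
    """Score every record of a cohort, keyed by patient id."""
    if variant == "base":
        return {
            r.patient_id: mews_base(r, table, max_carry_h) for r in cohort
        }
    if t_mews is None:
        raise ValueError(f"variant {variant!r} requires t_mews")
    return {
        r.patient_id: mews_interval(r, t_mews, variant, table, max_carry_h)
        for r in cohort
    }
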