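"""Synthetic case/control vital-sign cohorts.

Hospital EHR extracts of this kind are not publicly deposited, so the
generator emulates the structural features the evaluators depend on:

* right-skewed lengths of stay, log-normal per group, moment-matched to
  a printed median and IQR (case 86.3 h / 245.9 h; control 160.9 h /
  193.2 h);
* irregular per-parameter sampling from Poisson processes at per-group
  mean rates (case: GCS 0.3, TEMP 1, SBP 1.2, RR 2, HR 2.2 per hour;
  control: 0.1, 0.4, 0.5, 0.7, 0.8);
* baseline values stationary inside the zero-point scoring bands;
* a plantable pre-event deterioration signal in case patients —
  piecewise-linear drift into the scoring bands plus Gaussian noise —
  whose interval relative to the event is fully controllable, so
  sensitivity-recovery experiments can place it inside or before the
  prediction horizon;
* optional whole-record parameter dropout.

Values are i.i.d. around their (possibly drifting) mean by default; an
AR(1) switch adds serial correlation for robustness experiments only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from mewskit.alarms import EvalConfig
from mewskit.cohort import MANDATORY, PARAMETERS, Cohort, PatientRecord

__all__ = ["GeneratorSpec", "simulate_cohort", "plant_window_signal",
           "lognormal_from_median_iqr"]

#: z-score of the 75th percentile of the standard normal.
_Z75 = 0.6744897501960817


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a given median and inter-quartile range.

    For LogNormal(mu, sigma): median = exp(mu) and
    IQR = 2 * exp(mu) * sinh(z75 * sigma), which inverts in closed form.
    """
    if median <= 0 or iqr <= 0:
        raise ValueError("median and iqr must be positive")
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75
    return mu, sigma


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterisation of the synthetic cohort generator.

    ``los`` holds per-group (median, IQR) of the length of stay in
    hours; ``sampling_rates`` per-group mean measurements per hour;
    ``baseline`` per-parameter (mean, sd) of the stationary normal
    values; ``drift`` the per-parameter deterioration deltas reached at
    full ramp; ``onset_h``/``release_h`` delimit the deterioration
    interval [t_event - onset_h, t_event - release_h]; ``missingness``
    gives per-parameter whole-record dropout probabilities.
    """

    n_case: int = 50
    n_control: int = 250
    los: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"case": (86.3, 245.9), "control": (160.9, 193.2)}
    )
    sampling_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "case": {"GCS": 0.3, "TEMP": 1.0, "SBP": 1.2, "RR": 2.0, "HR": 2.2},
            "control": {"GCS": 0.1, "TEMP": 0.4, "SBP": 0.5, "RR": 0.7, "HR": 0.8},
        }
    )
    baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SBP": (115.0, 18.0),
            "HR": (82.0, 14.0),
            "RR": (14.0, 4.0),
            "TEMP": (36.9, 0.55),
            "GCS": (14.6, 0.7),
        }
    )
    drift: Mapping[str, float] = field(
        default_factory=lambda: {
            "SBP": -55.0,
            "HR": 60.0,
            "RR": 19.0,
            "TEMP": 2.0,
            "GCS": -11.0,
        }
    )
    onset_h: float = 8.0
    release_h: float = 0.0
    ramp_fraction: float = 0.3
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in PARAMETERS}
    )
    min_stay_h: float = 2.0
    ensure_scoreable: bool = True
    ar1: float = 0.0  # serial correlation of value noise; 0 = i.i.d.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")
        for g, rates in self.sampling_rates.items():
            for p, r in rates.items():
                if r <= 0:
                    raise ValueError(f"sampling rate {g}/{p} must be > 0")
        if self.onset_h < 0 or self.release_h < 0:
            raise ValueError("deterioration offsets must be >= 0")
        if self.onset_h < self.release_h:
            raise ValueError("onset_h must be >= release_h")
        for p, q in self.missingness.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"missingness {p} must be in [0, 1]")
        if not 0.0 <= self.ramp_fraction <= 1.0:
            raise ValueError("ramp_fraction must be in [0, 1]")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["los"] = {g: list(v) for g, v in self.los.items()}
        d["sampling_rates"] = {g: dict(v) for g, v in self.sampling_rates.items()}
        d["baseline"] = {p: list(v) for p, v in self.baseline.items()}
        d["drift"] = dict(self.drift)
        d["missingness"] = dict(self.missingness)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorSpec":
        d = dict(d)
        if "los" in d:
            d["los"] = {g: tuple(v) for g, v in d["los"].items()}
        if "baseline" in d:
            d["baseline"] = {p: tuple(v) for p, v in d["baseline"].items()}
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _ramp(times: np.ndarray, t_end: float, onset: float, release: float,
          ramp_fraction: float) -> np.ndarray:
    """Deterioration intensity in [0, 1] at each time.

    Zero outside [t_end - onset, t_end - release]; inside, rises
    linearly from 0 to 1 over the first ``ramp_fraction`` of the
    interval, then holds at 1.
    """
    start = t_end - onset
    stop = t_end - release
    length = stop - start
    out = np.zeros(len(times))
    if length <= 0:
        return out
    inside = (times >= start) & (times <= stop)
    if ramp_fraction > 0:
        rise = np.clip((times - start) / (ramp_fraction * length), 0.0, 1.0)
    else:
        rise = np.ones(len(times))
    out[inside] = rise[inside]
    return out


def _draw_values(
    rng: np.random.Generator,
    times: np.ndarray,
    param: str,
    spec: GeneratorSpec,
    group: str,
    t_end: float,
) -> np.ndarray:
    mean, sd = spec.baseline[param]
    noise = rng.normal(0.0, sd, size=len(times))
    if spec.ar1 > 0 and len(times) > 1:
        for i in range(1, len(noise)):
            noise[i] = spec.ar1 * noise[i - 1] + math.sqrt(1 - spec.ar1**2) * noise[i]
    values = mean + noise
    if group == "case":
        delta = spec.drift.get(param, 0.0)
        if delta != 0.0 and spec.onset_h > spec.release_h:
            values = values + delta * _ramp(
                times, t_end, spec.onset_h, spec.release_h, spec.ramp_fraction
            )
    if param == "GCS":
        values = np.clip(np.round(values), 3, 15)
    else:
        # keep values inside the validated physical ranges
        from mewskit.cohort import DEFAULT_BOUNDS

        lo, hi = DEFAULT_BOUNDS[param]
        values = np.clip(values, lo, hi)
    return values


def simulate_cohort(spec: GeneratorSpec) -> Cohort:
    """Generate a synthetic cohort according to ``spec``.

    Per patient: the stay is drawn from the group's log-normal (floored
    at ``min_stay_h``); each parameter's measurement times come from a
    Poisson process at the group rate; values are baseline draws with,
    for cases, the configured deterioration drift before the event.
    Case events sit at the recording end.  Identical spec and seed give
    identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    for group, n, prefix in (
        ("case", spec.n_case, "case"),
        ("control", spec.n_control, "ctrl"),
    ):
        mu, sigma = lognormal_from_median_iqr(*spec.los[group])
        for i in range(n):
            t_end = max(float(rng.lognormal(mu, sigma)), spec.min_stay_h)
            samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for param in PARAMETERS:
                if rng.random() < spec.missingness.get(param, 0.0):
                    continue
                rate = spec.sampling_rates[group][param]
                n_obs = rng.poisson(rate * t_end)
                if n_obs == 0 and spec.ensure_scoreable and param in MANDATORY:
                    n_obs = 1
                if n_obs == 0:
                    continue
                times = np.sort(rng.uniform(0.0, t_end, size=n_obs))
                values = _draw_values(rng, times, param, spec, group, t_end)
                samples[param] = (times, values)
            records.append(
                PatientRecord(
                    patient_id=f"{prefix}_{i:04d}",
                    group=group,
                    t_end=t_end,
                    samples=samples,
                )
            )
    return Cohort(
        records=records,
        metadata={"source": "synthetic", "seed": spec.seed, "spec_hash": spec.digest()},
    )


def plant_window_signal(
    spec: GeneratorSpec,
    config: EvalConfig,
    placement: Literal["inside_horizon", "before_horizon"],
) -> GeneratorSpec:
    """Derive a spec whose deterioration interval has a known placement.

    ``inside_horizon`` puts the drift interval strictly inside the
    prediction horizon [t_event - tau0 - tau, t_event - tau0];
    ``before_horizon`` ends it a full horizon length before the horizon
    starts — the gap must exceed the refresh timescale of the slowest
    parameter, or carried-forward deteriorated values would bleed into
    the horizon and alarm there.  The minimum stay is raised so the
    planted interval fits every case, enabling clean
    sensitivity-recovery experiments.
    """
    if config.tau is None or config.tau <= 0:
        raise ValueError("planting a window signal requires a finite tau > 0")
    tau, tau0 = config.tau, config.tau0
    if placement == "inside_horizon":
        onset = tau0 + 0.9 * tau
        release = tau0 + 0.1 * tau
    elif placement == "before_horizon":
        release = tau0 + 2.0 * tau
        onset = release + 0.8 * tau
    else:
        raise ValueError(f"unknown placement {placement!r}")
    min_stay = max(spec.min_stay_h, onset + 0.1 * tau)
    return dataclasses.replace(
        spec, onset_h=onset, release_h=release, min_stay_h=min_stay
    )
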