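import numpy as np
import pytest

from mewskit.cohort import Cohort, PatientRecord
from mewskit.scoring import ScoreSeries


def make_record(
    patient_id="p1",
    group="control",
    t_end=24.0,
    **param_samples,
):
    """Build a PatientRecord from keyword samples.

    Each parameter is given as a list of (time, value) pairs, e.g.
    ``HR=[(1, 70), (2, 80)]``.
    """
    samples = {}
    for param, pairs in param_samples.items():
        if not pairs:
            continue
        t = np.array([p[0] for p in pairs], dtype=float)
        v = np.array([p[1] for p in pairs], dtype=float)
        order = np.argsort(t, kind="stable")
        samples[param] = (t[order], v[order])
    return PatientRecord(patient_id=patient_id, group=group, t_end=t_end, samples=samples)


def make_series(patient_id, times, totals, group_unused=None):
    """Bare ScoreSeries with given totals (no subscores), for alarm tests."""
    return ScoreSeries(
        patient_id=patient_id,
        times=np.asarray(times, dtype=float),
        totals=np.asarray(totals, dtype=int),
        subscores={},
        imputed={},
        avpu_present=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def normal_vitals():
    """One fully sampled, all-normal patient (score 0 everywhere)."""
    return make_record(
        patient_id="ctrl_norm",
        group="control",
        t_end=10.0,
        SBP=[(1, 120), (5, 118)],
        HR=[(1, 72), (4, 80)],
        RR=[(1, 12), (6, 13)],
        TEMP=[(1, 36.8)],
        GCS=[(1, 15)],
    )


def random_series_cohort(rng, n_cases=4, n_controls=6, max_len=30):
    """A cohort of bare records plus random integer score series."""
    records, series = [], {}
    pid = 0
    for group, n in (("case", n_cases), ("control", n_controls)):
        for _ in range(n):
            pid += 1
            name = f"{group}_{pid}"
            t_end = float(rng.uniform(10, 60))
            n_scores = int(rng.integers(1, max_len))
            times = np.sort(rng.uniform(0, t_end, n_scores))
            times = np.unique(times)
            totals = rng.integers(0, 15, len(times))
            records.append(
                PatientRecord(patient_id=name, group=group, t_end=t_end, samples={})
            )
            series[name] = make_series(name, times, totals)
    return Cohort(records=records), series
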