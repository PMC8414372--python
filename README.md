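# mewskit

Evaluation toolkit for clinical predictive alarm indices, built around the
Modified Early Warning Score (MEWS) applied to the prediction of acute
deterioration events (e.g. in-hospital code blue) from irregularly sampled
vital signs.

Conventional validation of early-warning scores reports sensitivity,
specificity and AUC from a per-patient "did the score ever cross the
threshold" reduction.  That reduction ignores *when* alarms fire and *how
many* of them a care team must absorb — an alarm a week before a cardiac
arrest and an alarm ten seconds before it both count as true predictions.
`mewskit` implements, alongside the conventional scheme, an event-level
evaluation that scores alarms against an actionable time window and
quantifies the false-alarm burden.  It is aimed at researchers validating
early-warning or other continuous predictive alarm algorithms.

## What it computes

**Scoring.**  MEWS assigns 0–3 points to systolic blood pressure, heart
rate, respiratory rate, temperature and consciousness (AVPU, derived from
the Glasgow Coma Score: Alert = 14–15, Voice = 10–13, Pain = 4–9,
Unresponsive = 3) and sums them (maximum 14).  Three series variants are
supported for irregular EHR data, all with last-observation-carried-forward
(LOCF) imputation:

* `base` — re-score at every parameter refresh;
* `median` — score the element median of each parameter over regular
  intervals of length `T_MEWS`;
* `worst` — score the points-maximising measurement in each interval.

**Alarms.**  An alarm is an instantaneous notification wherever the score
strictly exceeds a threshold *k*.  For a case patient with event time
*t*<sub>event</sub>, a *prediction horizon* [*t*<sub>min</sub>,
*t*<sub>max</sub>] of length τ and a *lead time* τ₀ = *t*<sub>event</sub> −
*t*<sub>max</sub> partition alarms into **early** (before *t*<sub>min</sub>),
**on-time** (inside the horizon), **late** (inside the lead time) and
**post-event**; only on-time alarms are true alarms.

**Metrics.**

* time-dependent sensitivity  S<sup>τ,τ₀</sup> = N<sub>predicted events</sub> / N<sub>events</sub>,
  an event counting as predicted if at least one alarm fell in its horizon;
* bootstrapped false-positive ratio
  μ̂<sub>FPR</sub> = Σᵢ Σⱼ T<sub>ij</sub> / (N·M), where T<sub>ij</sub>
  indicates that the *j*-th of M random τ-length windows in control *i*
  contained an alarm, with replicate-derived ACC/PPV/NPV/F1;
* work-up to detection ratio WDR = (N<sub>case</sub> + μ̂<sub>FP</sub>) /
  N<sub>case</sub> — the number of patients worked up per detected event —
  with a standard deviation composed from per-control bootstrap spread;
* alarm burden per patient: alarm rate r = N<sub>alarms</sub>/T, alarm
  proportion ρ = N<sub>MEWS>k</sub>/N<sub>MEWS≥0</sub>, and false-alarm
  counterparts r⁰, ρ⁰ (case denominator T − τ);
* pooled alarm time profiles over early / on-time / late alarms and missed
  events, normalised per alarm or per event;
* the conventional patient-level confusion matrix, metric panel and
  ROC / precision-recall sweep over all 14 discrete thresholds.

Because the hospital records such methods are developed on are not publicly
available, the package ships a synthetic cohort generator with group-level
length-of-stay distributions, per-parameter Poisson sampling rates, and a
plantable pre-event deterioration signal, so every evaluator can be
exercised and stress-tested end to end.

## Worked example

```python
from mewskit import EvalConfig, GeneratorSpec, simulate_cohort, evaluate_cohort

spec = GeneratorSpec(n_case=30, n_control=150, seed=7)
cohort = simulate_cohort(spec)

config = EvalConfig(k=4, tau=12.0, tau0=1.0, M=1000, seed=7)
report = evaluate_cohort(cohort, config)

pl = report["patient_level"]["metrics"]
ev = report["event_level"]
print(f"patient-level: TPR={pl['TPR']:.2f}  FPR={pl['FPR']:.2f}  "
      f"PPV={pl['PPV']:.2f}  WDR={pl['WDR']:.1f}")
print(f"event-level:   S={ev['sensitivity']['S']:.2f}  "
      f"FPR={ev['bootstrap_fpr']['mean']:.2f} (sd {ev['bootstrap_fpr']['std']:.2f})  "
      f"WDR={ev['WDR']['mean']:.1f} (sd {ev['WDR']['std']:.2f})")
prof = ev["time_profiles"]["per_alarm"]
print(f"alarm profile: early={prof['early']:.2f}  on_time={prof['on_time']:.2f}  "
      f"late={prof['late']:.2f}  missed={prof['missed_events']:.2f}")
```

prints

```
patient-level: TPR=1.00  FPR=0.52  PPV=0.28  WDR=3.6
event-level:   S=1.00  FPR=0.06 (sd 0.23)  WDR=1.3 (sd 0.09)
alarm profile: early=0.27  on_time=0.61  late=0.11  missed=0.00
```

Read: with an any-crossing patient-level evaluation, half the control
patients count as false positives (FPR 0.52) and 3.6 patients must be
worked up per detected event.  Restricting true alarms to a 12 h horizon
with a 1 h lead time, the expected fraction of controls whose random 12 h
window contains an alarm drops to 0.06 and the work-up ratio to 1.3,
while every event is still caught (S = 1.00); 61% of case alarms fall
inside the horizon.

The same pipeline is available from the shell:

```sh
mewskit simulate --n-case 30 --n-control 150 --seed 7 --out cohort.csv
mewskit score cohort.csv --variant worst --t-mews 2 --out scores.csv
mewskit evaluate cohort.csv --k 4 --tau 12 --tau0 1 --m 1000 --seed 7 --out report.json
```

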