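# Methods

This note documents the models, estimators and conventions implemented in
`mewskit`, the choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not demonstrate.

## Scoring model

MEWS sums 0–3 point assignments over five parameters; the default table
gives a maximum of 14 (SBP 3, HR 3, RR 3, TEMP 2, AVPU 3).  Consciousness
enters through the Glasgow Coma Score with the one-to-one AVPU mapping
Alert = GCS 14–15, Voice = 10–13, Pain = 4–9, Unresponsive = 3, encoded
directly as GCS bands.

The familiar printed form of the table uses integer band labels (e.g.
SBP 71–80, heart rate 101–110) that leave real-valued gaps.  Bands here
are made contiguous by treating the lower-severity band as half-open at
each shared edge: SBP ≤70 → 3, (70, 80] → 2, (80, 100] → 1,
(100, 200) → 0, ≥200 → 2; HR ≤40 → 2, (40, 50] → 1, (50, 100] → 0,
(100, 110] → 1, (110, 130) → 2, ≥130 → 3; RR <9 → 2, [9, 15) → 0,
[15, 21) → 1, [21, 30) → 2, ≥30 → 3; TEMP <35 → 2, [35, 38.5) → 0,
≥38.5 → 2.  This preserves every printed integer label while defining
every real value.  The table is configuration data (`ScoringTable`), so
an alternative convention — or a different early-warning score — can be
supplied without code changes; no alternative preset is shipped as
validated.

### Series variants and imputation

* `base`: a new total at every distinct measurement time of any
  parameter (a GCS refresh alone also triggers re-scoring), with every
  other parameter carried forward from its last measurement (LOCF).  No
  score is emitted before each of SBP/HR/RR/TEMP has been observed once;
  records in which one of these was never measured are excluded, with a
  machine-readable report.  GCS is optional: when absent, the AVPU term
  is omitted and totals are capped at 11 by construction.
* `median` / `worst`: scores on a regular grid anchored at admission and
  stamped at interval ends T, 2T, … ≤ t_end (end-stamping avoids
  look-ahead).  Interval j covers ((j−1)T, jT]; a t = 0 measurement is
  assigned to the first interval.  The *median* summary is the lower
  element median — always an observed value, so the dominance invariant
  below is exact; an interpolated median could fall in a band no
  measurement occupies.  The *worst* summary is the in-interval value
  maximising that parameter's points (the only score-relevant reading of
  "worst"), ties broken by the most recent measurement.  An interval
  with no new measurement falls back to the last recorded value, flagged
  imputed.

Because the worst summary maximises points over a set containing the
element median, `worst` subscores — and therefore totals — dominate
`median` at every aligned time.  This ordering is enforced by property
tests.

LOCF has no expiry by default, consistent with carrying slow-changing
parameters indefinitely; `max_carry_h` optionally expires stale values
(an expired mandatory parameter suppresses the score sample, an expired
GCS drops only the AVPU term).

## Alarm model

An alarm fires at every score sample with total strictly greater than
the threshold k (hence the meaningful sweep k = 0…13); there is no
grouping, lockout or escalation.  For a case patient the recording ends
at the event, t_event = t_end, and with horizon length τ and lead time
τ₀: t_max = t_event − τ₀, t_min = t_max − τ.  The on-time interval is
closed ([t_min, t_max]) — an alarm exactly at t_max still leaves the
full lead time — and late is the open interval (t_max, t_event).
Post-event alarms cannot occur in event-truncated records but are
labelled and counted as false for generality.  `tau = None` denotes a
per-record full-stay horizon (τ = t_event), the limit in which every
pre-event alarm is on-time and event-level sensitivity coincides exactly
with patient-level TPR; this limit is checked on random cohorts.

## Estimators

**Time-dependent sensitivity.**  S = N_predicted / N_events over case
patients with t_event ≥ τ + τ₀ (shorter stays cannot host the window and
are excluded, reported by id); an event is predicted iff it has ≥ 1
on-time alarm.

**Bootstrap FPR.**  For each control with recording length ≥ τ, M window
starts are drawn uniformly on [0, T − τ], time-ordered, and paired
across patients by rank index j (the pairing is immaterial for the mean
because the draws are i.i.d., but it makes replicate-level metrics
reproducible).  T_ij ∈ {0, 1} records whether window j of control i
contains an alarm; the estimate is the grand mean.  The per-window-index
deviation entering the composed standard deviation is, by default, the
sample standard deviation of the binary hits across controls (the
standard binomial estimator); a `variance="literal"` switch instead
measures deviations of the binary hits from the per-window *count* of
hits, a dimensionally inconsistent form retained only for comparability
with prior formulations.  Either deviation is composed as the root mean
square over the M window indices.  Means are verified against a
closed-form oracle: the exact hit probability is the measure of the
union of intervals [a − τ, a] (a ranging over alarm times) clipped to
[0, T − τ], divided by T − τ.

**Replicate-derived metrics.**  For window index j, a confusion matrix
combines the fixed case outcomes (N_predicted of N_events) with the j-th
control column (Σᵢ T_ij false positives among N controls); FPR, PPV,
NPV, ACC and F1 are computed per replicate and summarised by mean and
sample standard deviation across the M replicates (zero by convention at
M = 1; replicates with a zero denominator are skipped and counted).

**WDR.**  With μ̂ᵢ and σ̂ᵢ the per-control mean and standard deviation of
T_ij over j: mean = 1 + Σμ̂ᵢ / N_case_predicted and
std = √(Σσ̂ᵢ²) / N_case_predicted; undefined (NaN) with zero predicted
cases.  Controls contribute to FPR and WDR only; case-side false alarms
enter only the burden metrics and profiles.

**Burden.**  Per patient, r = N_alarms / T and ρ = N_alarms / N_scores.
False alarms are all alarms for controls, and the early + late +
post-event classes for cases, whose rate denominator is T − τ (no false
alarm can occur inside the horizon by definition; flagged NaN when
T ≤ τ).  With τ = τ₀ = 0 every alarm is false and r⁰ = r, ρ⁰ = ρ.

**Time profiles.**  Early / on-time / late counts pooled over case
patients; missed events are cases with no on-time alarm.  The per-alarm
profile normalises the three alarm classes by the total pre-event alarm
count (they sum to 1); missed events are normalised per event in both
profiles, as they count events rather than alarms.

**Patient-level panel.**  Any-crossing confusion matrix; ratios with
zero denominators are returned as NaN flags rather than raised so full
threshold sweeps never abort.  The ROC is built from the 14 discrete
operating points plus the (0,0) and (1,1) anchors and integrated by
trapezoid; because the score is a 15-level integer this ROC is complete,
and the area provably equals the rank concordance (ties = ½) of the
per-patient maximum score, which an exhaustive pairwise oracle verifies
to 1e-12.  The PR curve uses the same points with a
(recall 0, precision 1) anchor; no interpolation beyond trapezoid.

## Synthetic cohorts

The generator reproduces the structural features the evaluators are
sensitive to, with defaults frozen as the package's study conditions:

* **Stays**: log-normal per group, matched in closed form to median/IQR
  targets of 86.3 h / 245.9 h (cases) and 160.9 h / 193.2 h (controls) —
  log-normality is a convention (strictly positive, right-skewed, two
  statistics fix two parameters), not an inference.  Stays are floored
  at 2 h to avoid degenerate records.
* **Sampling**: per-parameter homogeneous Poisson processes at group
  mean rates (case: GCS 0.3, TEMP 1, SBP 1.2, RR 2, HR 2.2 per hour;
  control: 0.1, 0.4, 0.5, 0.7, 0.8).  Scheduled-rounds clustering is
  deliberately not modelled.  A mandatory parameter drawn with zero
  events receives one uniformly placed measurement
  (`ensure_scoreable`), so exclusions are driven only by the explicit
  dropout mechanism.
* **Values**: i.i.d. normal around parameter baselines SBP 115 (18),
  HR 82 (14), RR 14 (4), TEMP 36.9 (0.55), GCS 14.6 (0.7) — means inside
  the zero-point bands, spreads wide enough that control patients
  occasionally cross alarm thresholds.  Degenerate always-silent
  controls would make the bootstrap, WDR and burden machinery vacuous;
  real ICU controls alarm frequently.  GCS is rounded and clipped to
  [3, 15]; vitals are clipped to the validation bounds.  An AR(1) switch
  adds serial correlation for robustness experiments only.
* **Deterioration**: case values drift piecewise-linearly from baseline
  to baseline + Δ (defaults: SBP −55, HR +60, RR +19, TEMP +2, GCS −11)
  over the first 30% of the interval [t_event − onset, t_event −
  release] (defaults 8 h to 0 h before the event), then hold; the
  minimal mechanism that moves values across scoring bands at a
  controllable time.
* **Dropout**: whole-record per-parameter removal with configured
  probability, verified by binomial test.

`plant_window_signal` derives specs whose drift interval lies strictly
inside the prediction horizon (onset τ₀ + 0.9τ, release τ₀ + 0.1τ) or
entirely before it.  The before-horizon placement leaves a gap of one
full horizon length (release = τ₀ + 2τ) between drift release and
horizon start: LOCF carries deteriorated values forward, and the slowest
parameter (case GCS at 0.3/h) needs several hours to refresh, so a
narrow gap would leak planted signal into the horizon and contaminate
the null.  Both placements raise the generator's minimum stay so the
planted interval fits every case.

**What passing tests show.**  On these cohorts, planted in-horizon
deterioration is recovered with S ≥ 0.95 at k = 4 and before-horizon
deterioration leaves on-time rates at the control window-hit rate
(rate-matched controls, 3σ).  Because values are i.i.d., sampling is
homogeneous Poisson and deterioration is a clean monotone drift, these
results demonstrate correctness of the evaluation machinery — not
clinical performance of MEWS, which depends on autocorrelated
physiology, state-dependent sampling and heterogeneous case mix that the
generator intentionally omits.

## Numerical conventions and problem sizes

* Time is continuous hours since admission; all windows use closed/open
  conventions as stated above; grid arithmetic uses a 1e-9 tolerance.
* Duplicate (patient, parameter, time) rows keep the last value (EHR
  correction semantics) and log the collision; within-parameter sorting
  is stable.
* A single `numpy` Generator seeded from the configuration drives each
  stochastic step; identical config + seed is bit-reproducible.
* Undefined ratios are NaN flags throughout, never exceptions.
* Test and acceptance problem sizes were chosen as the smallest at which
  each property is sharp: 5 constructed controls × M = 2000 for the
  bootstrap-vs-oracle check, 100 cohorts of 7 patients for the
  full-stay equivalence (an exact identity, so size is immaterial),
  200 cases for signal recovery, 100 + 100 for the before-horizon null,
  and 40 + 200 for the end-to-end pipeline run.

## Limitations

* Alarm grouping/lockout, adaptive thresholds and alarm surrogates are
  out of scope; every threshold crossing is an alarm, which upper-bounds
  burden relative to deployed systems.
* The patient-level/event-level comparison on synthetic data tracks the
  direction, not the magnitude, of differences observable on real EHR
  cohorts.
* Multi-admission linkage, timezone-aware timestamps and FHIR/HL7
  ingestion are not supported; input is the long CSV format only.
* The per-patient reduction behind the ROC sweep is the maximum score
  over the stay; other reductions (e.g. mean score) are not implemented.
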