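# actidaily

Bidirectional daily associations between adolescent sleep and physical
activity, from raw dual-device actigraphy to multilevel estimates.

Micro-longitudinal studies ask whether a day with more moderate-to-vigorous
physical activity (MVPA) is followed by earlier, longer or more efficient
sleep that night — and whether a night's sleep shapes the next day's
activity.  Answering this from wearables takes a long pipeline: a wrist
accelerometer scored into nightly sleep intervals, a hip accelerometer
classified into minute-level activity types, the two devices merged on
"days" anchored at successive sleep onsets, and a panel model that
separates a person's stable habits from their day-to-day fluctuations.
`actidaily` implements that pipeline end to end, together with a
synthetic-cohort generator with known ground truth so every stage — and the
estimator itself — is testable without access to any cohort's raw data.

## What it computes

**Sleep scoring (wrist, 30-s epochs).**  An epoch is *active* when its
count exceeds 10.  Sleep onset is the last active epoch followed by 5
consecutive quiet epochs; offset is the first active epoch following 5
quiet ones.  Awakenings ≥ 1 h split an interval; the interval with the
longest duration touching 10 PM–8 AM of a noon-to-noon day is that night's
main sleep, the rest are naps.  Nightly metrics: onset (midnight-centered
hours), offset (24-h clock), duration (min), and sleep maintenance
efficiency, SME = 100 × sleep minutes / duration.  Days with ≥ 4 h
off-wrist, too little wear before the first onset, or a ≥ 60-min off-wrist
run within 10 min of a sleep edge are invalid.

**Activity classification (hip, 1-s counts).**  Non-wear is ≥ 90 min of
zero-count minutes, tolerating ≤ 2-min nonzero spikes flanked by ≥ 30 zero
minutes.  Each worn minute is summarized by the 10/25/50/75/90th count
percentiles and the lag-one autocorrelation of its sixty 1-s counts, then
labeled sedentary / light / moderate-vigorous / walking / running by a
pluggable classifier (a reference network trained on synthetic labeled
minutes ships with the package); MVPA collapses the last three classes.

**Day alignment.**  A day runs from one night's sleep onset to the next
(10 PM onset → 11:30 PM onset = a 25.5-h day).  Daily MVPA and sedentary
minutes are counted over the wake portion, with sedentary minutes inside
scored naps excluded; days with > 25% non-wear, or force-ended days
shorter than 20 h, are invalid.  The densest 120-min MVPA window, its
midpoint, and daytime light (lux) summaries are also computed.

**Estimation.**  For outcome `y` of person *i* on day *t*, with the focal
daily predictor `x` split into between- and within-person components,

```
y_it = β₀ + β_b (x̄_i − x̄) + β_w (x_it − x̄_i) + γ′z_i + δ·weekend_t + u_i + e_it
u_i ~ N(0, σ²_u),   cov(e_it, e_is) = σ²_e ρ^|t−s|
```

is fit by maximum likelihood with β profiled out by GLS (REML optional).
Sixteen models cover both directions: {onset, offset, duration, SME} ×
{MVPA, sedentary} as outcomes and as (one-day-lagged) predictors.  The
within-person coefficient β_w answers the daily question: e.g.
β_w = −0.005 h per MVPA minute means a one-hour MVPA increase above one's
own average predicts an 18-minute earlier sleep onset (−0.005 × 60 × 60).

## Worked example

```bash
actidaily run-all --synthetic --seed 1 --out demo
actidaily report --bundle demo
```

prints (abridged):

```
Cohort descriptives (valid person-days)
==========================================
participants: 10, person-days: 70
Sleep Onset (time)                     00:12 (SD 0.89 h)
Sleep Offset (time)                    07:50 (SD 1.19 h)
Sleep Duration (min)                   458.5 (45.5)
Sleep Maintenance Efficiency (%)       89.8 (2.7)
MVPA (min)                             48.0 (24.7)
Sedentary Time (min)                   383.1 (69.6)

Within-person focal coefficients
==========================================
sedentary_min -> onset_mc_h: B=+0.0043 (SE 0.0013, p=0.000752); per hour: +15.5 min
...
```

The descriptive block recovers the generator's configured schedule (onset
near midnight, ~7:50 offset, ~45 MVPA and ~390 sedentary minutes).  Each
model line reports the within-person coefficient on its native scale plus
the per-hour effect: here a one-hour increase in sedentary time above a
person's average predicts a 15.5-minute later sleep onset that night in
this small demo cohort.  With ten participants most coefficients are
insignificant; the parameter-recovery tests run the same estimator at
400 × 7 where the generating coupling is recovered with nominal coverage.

The same stages are available piecemeal (`synth`, `score-sleep`,
`classify-activity`, `align`, `model`) over delimited-text files, and as
library functions (`generate_cohort`, `score_participant`, `process_hip`,
`build_person_days`, `fit_lmm_ar1`, `run_model_suite`).

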