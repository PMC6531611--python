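# Methods

This note documents the models, rules, parameters and design choices
behind `actidaily`, in the order the pipeline runs.

## Synthetic cohorts

### Daily structural model

The generator's first stage draws, per participant *i* and day *t*, five
daily outcomes — sleep onset (midnight-centered hours), sleep offset
(hours since midnight), sleep maintenance efficiency (SME, %), MVPA
minutes and sedentary minutes — from

```
value_it = base + u_i + weekend_t · w + Σ_pred c_pred · dev_pred + e_it
```

with person intercepts `u_i ~ N(0, σ²_between)`, stationary AR(1)
residuals `e_it` (`e_t = ρ e_{t−1} + √(1−ρ²) σ z_t`), and coupling
coefficients `c` multiplying the *realized deviation of the lagged
predictor from that person's latent mean* (`dev = value − base − u_i`).
Generation is sequential in time: night 0, day 0 (influenced by night 0),
night 1 (influenced by day 0), and so on, which matches the lagged model
specifications exactly.  Sleep duration is derived, `(offset − onset) ×
60`, so duration couplings emerge from the onset/offset ones rather than
being separately injectable.

Couplings act on the full realized deviation (weekend shift included)
because that is the quantity a within-person decomposition of the daily
panel observes; defining them net of the weekend shift would leave an
omitted weekend-of-the-predictor-day term in the outcome equation and
visibly attenuate recovery.

The configured means are *marginal* cohort means.  Because start weekdays
are staggered (participant *i* starts `i mod 7` days after the base
Monday), the weekend fraction is exactly 2/7, and the baseline absorbs
both the expected weekend shift and the expected coupling contribution
(computed as a short fixed-point over the couplings) so that cohort tables
reproduce the configured values.

Default parameters (units; chosen to emulate a school-year adolescent
cohort's published descriptive statistics, with between-person SDs free
parameters set for plausible totals since no variance decomposition is
reported):

| parameter | default | notes |
|---|---|---|
| onset mean | +0:04 h | midnight-centered |
| offset mean | 7:49 h | |
| SME mean | 90.9 % | |
| MVPA mean | 45.3 min/day | |
| sedentary mean | 390 min/day | |
| between-person SDs | 0.9 h / 0.9 h / 2 % / 15 min / 60 min | onset, offset, SME, MVPA, sedentary |
| residual SDs | 0.6 h / 0.6 h / 1.8 % / 18 min / 65 min | day-to-day |
| AR(1) ρ | 0.2 | day-index distance |
| weekend shifts | +0.93 h, +1.86 h, 0, −21 min, −18 min | Friday/Saturday nights; Saturday/Sunday days |
| onset–offset correlation | 0.7 between, 0.5 within | late sleepers wake late |
| default couplings | the published within-person estimates | e.g. MVPA→onset −0.005 h/min |

Onset and offset intercepts and innovations are drawn correlated so that
the derived duration SD (~55 min) is realistic rather than the sum of two
independent variances.  Values are clipped to physical ranges (onset in
[−6, 10] h, offset in [onset+3, onset+14] h, SME in [55, 100], activity in
[0, 800] min); clipping binds rarely (≈10% of weekend MVPA days at 0) and
the realized value is what enters both the truth tables and the coupling
chain, so no inconsistency is introduced.

### Rendering to device streams

A cohort of *n* days renders *n*+1 nights per participant: the recording
starts 3 h before the first onset and ends 90 min into the terminal night,
whose onset closes the last person-day (so *n* wear days yield *n*
person-day records, the last force-ended at the terminal onset — the same
accounting as a week-long protocol).

Wrist (30-s epochs): daytime counts are `20 + Poisson(150)` (never
quiet), sleep counts `min(Poisson(1.2), 10)`; the epoch at onset stays
active (it *is* the "last active epoch") and the epoch at offset is the
first active one, so the scoring rules recover the rendered instants
exactly on clean data.  Brief nocturnal arousal bouts (2–6 epochs of
active counts, ≥ 10 min from the interval edges, ≥ 6 quiet epochs apart)
realize the night's target SME.  Daytime lux is Gamma(2, 150), night lux
uniform on [0, 3].

Hip (1-s counts): minute labels are placed on the day grid — MVPA in
bouts of 5–20 min (raw class moderate-vigorous/walking/running at
0.4/0.4/0.2), sedentary in blocks of 20–60 min, the rest light — then each
contiguous same-label run is rendered as an AR(1) count process with
class-specific mean/persistence/innovation (sedentary and sleep: 90%
zeros, otherwise Poisson(3)).  The classes are learnable from the
60-s percentile + lag-1-autocorrelation features but overlap enough that a
trivial threshold will not separate them.

Optional realism: naps (30–90 min quiet wrist windows, default off),
injected non-wear gaps of 90–180 min applied to both devices (hip counts
zeroed; wrist off-wrist flag set), after which the ground-truth daily
totals are recomputed from the surviving labeled minutes.

What the generator does **not** emulate: raw tri-axial waveforms,
seasonal/photoperiod structure, device clock drift, asynchronous device
removal, and behaviourally realistic activity textures (the classes are
parametric count processes).  Passing tests therefore demonstrate that the
pipeline implements its rules faithfully and that the estimator is
calibrated under the generating model — not that the reference classifier
would reach the same accuracy on field recordings.

## Sleep scoring

Thresholds (all exposed in `ScoringParams`): active means counts > 10 per
30-s epoch; onset = last active epoch followed by 5 quiet epochs; offset =
first active epoch after 5 quiet.  The onset timestamp convention is
`onset_epoch="active"` (the active epoch's start time, the rule's literal
reading); `"quiet"` reports the first quiet epoch, 30 s later.  Off-wrist
epochs are excluded from scans — they break quiet runs and can anchor
nothing, so non-wear zeros cannot fake sleep.

The published protocol had trained human scorers bracket candidate rest
periods before applying the onset/offset rules; the automatic wrapper used
here derives candidate rest periods from immobility: quiet runs are
grouped into regions bounded by non-quiet runs of ≥ 60 min (the same
threshold as the awakening-split rule, so the two stages cannot disagree),
and a region qualifies when it holds ≥ 20 min of total quiet.  Regions are
trimmed to their first/last quiet epoch and padded with 10 min of context
for the scans.  Within a scored interval an epoch is asleep iff quiet
(reusing the count-10 threshold; the proprietary rescoring algorithm is
unpublished), awakenings of ≥ 120 consecutive wake epochs split it, and
each piece is re-scored.

Main sleep: intervals are assigned to noon-to-noon cut-point days by their
onset; among intervals overlapping the 22:00–08:00 window the one with the
longest *total* duration wins (tie → larger overlap, then earlier onset).
"Longest duration between the hours" is ambiguous between total and
in-window duration; both are implemented (`main_sleep_duration`), total is
the default.  Validity: ≥ 240 min off-wrist invalidates a (non-first/last)
day; the first day needs ≥ 120 worn minutes before onset; an off-wrist run
of ≥ 60 min starting or ending within 10 min of the main onset/offset
invalidates the day.

## Activity processing

Non-wear: 1-s counts are summed into clock minutes; an interval of zero
minutes of ≥ 90 min is non-wear, tolerating interior nonzero spikes of
≤ 2 min when immediately flanked by ≥ 30 consecutive zero minutes on both
sides.  Edge semantics (spikes near interval ends) follow the brute-force
enumeration oracle in the test suite.  Features per worn minute: empirical
10/25/50/75/90th percentiles (linear interpolation between order
statistics — the convention is unstated upstream, so it is fixed and
documented here) and the lag-one autocorrelation `Σ(x_t−x̄)(x_{t+1}−x̄) /
Σ(x_t−x̄)²`, defined as 0 for zero-variance minutes.  Partial trailing
minutes are dropped with a log notice.

The published activity-type network's weights are not redistributable, so
a stand-in reference classifier — a standardized single-hidden-layer
network (16 units) trained on balanced synthetic labeled minutes,
deterministic given its seed — fills the same interface (features in, one
of five classes out); any estimator with `predict` can be swapped in.
MVPA is the collapse of moderate-vigorous, walking and running; light
minutes are carried but not analysed.  Non-wear minutes are removed from
the labeled output.

## Day alignment

A person-day spans main-sleep onset to the next calendar night's valid
main-sleep onset.  When that next night is missing or invalid, the day is
force-ended at the earlier of the first > 60-min off-wrist run or the
first apparent sleep interval after the morning offset, and marked; forced
days shorter than 20 h are invalid.  Daily totals count minutes *fully
contained* in the wake portion (a minute straddling the offset or the
terminating onset belongs to sleep); sedentary minutes overlapping a
scored daytime sleep interval by ≥ 30 s are excluded, and the > 25%
non-wear rule uses the nap-free wake portion as denominator (the rule's
denominator is unstated; the wake-portion reading is adopted).  The
weekend flag attaches to Friday/Saturday *nights* for sleep outcomes and
Saturday/Sunday *days* for activity outcomes; under onset-anchored days
these coincide on a record, matching the single weekend covariate used in
the models.

The densest-MVPA cluster slides a 120-min window in 1-min steps across the
daytime span; the midpoint is the center of the earliest maximizing
*window* by default (`cluster_midpoint="centroid"` reports the mean time
of the MVPA minutes inside it instead — the intended reading of
"midpoint" is ambiguous).  Inclusion: ≥ 3 *consecutive* valid sleep days
and ≥ 3 valid activity days; school-year selection keeps participants
whose first valid day falls in September–May.

## Mixed models

Sixteen models: {onset, offset, duration, SME} as outcomes of {MVPA,
sedentary} (activity lagged one day backward: day *t* activity → night
*t*+1 sleep, so each person's first night drops), and {MVPA, sedentary} as
outcomes of the same night-to-morning sleep (same record).  Every model
includes the focal predictor twice — between (person mean centered at the
sample mean of person means) and within (daily deviation from the person
mean; a one-day person contributes a zero) — plus weekend and, when a
covariate table is supplied, sex, age, race, mother's education, family
structure, income band and BMI percentile, one-hot with the conventional
reference levels (Female; White, non-Hispanic; Less than High School;
Biomother + Biofather; ≥ 300%).

Estimation maximizes the Gaussian likelihood of `y = Xβ + u_i + e` with
`u_i ~ N(0, σ²_u)` and `cov(e_t, e_s) = σ²_e ρ^|d_t − d_s|` where `d` is
the scored day index — missing days widen the gap; calendar hours are not
used.  β is profiled out by GLS; the three variance parameters are
optimized on (log σ²_u, log σ²_e, atanh ρ) by Nelder-Mead with multiple ρ
starts (−0.5, 0, 0.5) to avoid boundary-adjacent local optima.  Persons
sharing a day-spacing pattern share one covariance factorization, making
400 × 7 fits take ~0.3 s.  ML is the default; REML adds the usual
`−½ log|X'V⁻¹X|` correction.  Standard errors come from the GLS
information matrix and p-values are Wald z; no Satterthwaite-style
denominator-degrees-of-freedom correction is attempted (the upstream df
method is unstated), which makes small-sample p-values mildly liberal —
the type-I simulation at 100 × 7 sits near 0.05.  Boundary estimates
(|ρ| > 0.99, σ²_u ≈ 0) are reported with warnings; singular designs (e.g.
the full covariate set on a handful of participants) raise instead of
returning NaN standard errors.

Per-hour effect scaling multiplies a per-minute coefficient by 60 and
converts hour-scale outcomes to minutes (so −0.005 h/min → −18 min per
hour of the predictor).

## Verification strategy and problem sizes

Every rule with nontrivial edge semantics is checked against an
independent brute-force oracle: onset/offset against an exhaustive window
scan (1,000 random series), non-wear against direct interval enumeration
(500 series), the MVPA cluster against a full window sweep (200 days), and
the structured likelihood against dense multivariate-normal evaluation on
all toy cohorts up to 10 × 5 (tolerance 1e-8) and against R `nlme::lme`
with `corAR1` (coefficients, variance components and log-likelihood agree
to ≥ 6 decimals).  Estimator calibration uses 100 replicate 400 × 7
cohorts for bias/coverage of a −0.005 h/min coupling and 1,000 replicate
100 × 7 cohorts for the null rejection rate; these Monte-Carlo sizes keep
the full suite under five minutes while leaving Monte-Carlo error well
inside the acceptance bands.  Pipeline conservation (scored instants and
daily totals equal to ground truth) is exercised on rendered 6 × 7
cohorts, with and without naps, arousals and injected non-wear.

## Known limitations

- The reference classifier stands in for the published activity-type
  network; its accuracy transfers only within the synthetic texture model.
- Wake/sleep inside an interval reuses the count-10 threshold; proprietary
  weighted rescoring is not reproduced, so SME values are
  convention-dependent.
- No random slopes, non-Gaussian outcomes, or multiple-testing adjustment
  (the modeled suite applies none).
- Naive local timestamps; daylight-saving transitions and timezones are
  out of scope.
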