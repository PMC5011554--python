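# Methods

`legwork` analyses minute-sampled telemetry from a resistance leg-training
device: the temperature rise Δt° of its friction unit above the session-start
baseline, which proxies the user's leg work output (LWO), recorded alongside
fingertip-oximeter heart rate.  This note describes the models behind each
stage, the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Thermal model of the device

The friction unit heats in proportion to the instantaneous work rate and
cools toward ambient, so the sensor reading follows first-order
heating/cooling dynamics

    dΔ/dτ = α·P(τ) − λ·Δ(τ),    Δ(0) = 0,

with `P` the work rate in work-units/min (1.0 ≡ the mean participant's
moderate rate), `α` the gain (°C per work-unit) and `λ` the cooling rate
(1/min).  One mechanism reproduces both observed regimes:

* **High sensitivity** (`λ = 0.4`/min, `α = 13.68`): the trace plateaus
  within minutes at Δ* = αP/λ, so the plateau level reads out the work rate.
  The calibration anchors Δ* = 34.2 °C at unit power; at the 1.5× and 1.8×
  relative work rates of harder exercise the plateaus fall near 51 and
  57 °C.
* **Low sensitivity** (`λ = 2×10⁻⁴`/min, `α = 0.27081`): cooling is
  negligible over a session (λ·30 min = 0.006), the rise is effectively
  linear, and the value reached integrates the work done.  `α` is always
  recalibrated from `λ` so that a unit-power 30-minute bout accumulates
  exactly 8.1 °C — the study-scale mean daily dose.  We keep `λ` strictly
  positive but very small: any appreciable curvature makes the second half
  of a constant-rate bout systematically slower than the first (at
  λ = 0.01/min the effect is ~15%), which would mimic fatigue in
  fatigue-free afternoon sessions; at the default the residual
  half-difference is ~0.03 min, far below the resolution of the split-half
  statistic.

Integration is fixed-step (default 0.1 min) with the exact exponential
update for piecewise-constant input, `Δ' = Δe^{−λh} + (αP/λ)(1−e^{−λh})`,
so constant-power traces match the closed form to machine precision and the
0.5% accuracy bound holds trivially.  Minute-sampled power is linearly
interpolated onto substeps.  Sensor noise is additive Gaussian (default
0.1 °C high mode, 0.05 °C low mode), seeded.

The inverse model recovers the work-rate signal from a trace:
`P̂ = (dΔ/dτ + λΔ)/α`, the derivative taken by a centred least-squares
(Savitzky–Golay, degree 1) window.  The window defaults to 3 min in high
mode and 7 min in low mode: the low-mode slope is ~0.3 °C/min against
0.05 °C sample noise, so a 3-min derivative carries ~13% noise per sample —
enough to trip a 10% decline criterion spuriously — while 7 min brings it
under 4%.

Idle cooling between sessions uses a separate rate (0.05/min, time constant
20 min): the in-exercise low-mode `λ` reflects the weak sensor coupling to
the heat source, not the unit's ambient cooling, and the device visibly
returns to baseline between daily sessions.

## Synthetic exerciser model

A bout couples the thermal model to a simple performance model.

**Work rate and intensity.**  Heart-rate targets map to relative steady work
rates through anchors (100, 120, 130 BPM) → (1.0, 1.5, 1.8), interpolated
linearly.  A participant's `power_scale` multiplies this; the cohort
generator draws it from Normal(1.0, cv) truncated above 0.5, default
cv = 0.17, which propagates through the near-linear dose map to the
inter-individual dose spread (mean 8.1 °C, person-to-person range ≈ 7–10 °C).

**Fatigue.**  Under heart-rate control, onset is linear in the heart-rate
deficit below the vigorous reference: `T_f = 7 + 0.8·(130 − HR)` min
(7 min at HR 130, 15 at 120, 31 at 100 — hence a 30-minute moderate bout is
fatigue-free).  After onset the work rate declines linearly at
`fatigue_decay_rate` (default 0.0217/min of the fresh rate); the combined
fatigue-and-pacing loss is floored at 45% of the fresh rate.  The floor
matters: with a deep floor a bout whose threshold sits near the
participant's capacity crawls toward it, producing unrealistically
heavy-tailed completion times.  Under power control the natural decline is
denied, so intensity must rise instead: onset uses a separate anchor
(10 min of moderate HR at unit work rate) and HR then drifts upward at
1.5 BPM/min toward HR_max.

**Diurnal fatigability.**  Sessions starting at or after 17:00 divide the
onset by the participant's `evening_factor` and multiply the decay rate by
it.  The cohort default is a mild 1.3.  The home-program participant —
the individual studied in depth over 8 weeks — is a configured profile
(`power_scale = 1.3515`, prescription 10 °C, `evening_factor = 2.0`)
calibrated by Monte Carlo so that afternoon dose completions average
27.4 min with half-dose times ~13.5 min, evening completions average
~33.8–34.2 min, and the evening second half runs ~50% longer than the
first.  Carried-over fatigue (consecutive doses without rest) is modelled
by advancing onset by the minutes already exercised, which reproduces the
observed 27 → ~40 min lengthening of a second back-to-back dose.

**Between-bout variability.**  Three seeded jitters: a day-effort
multiplier on the work rate (CV 0.01), a slow within-bout pacing drift
(slope SD 5×10⁻⁴/min), and a lognormal multiplier on the decay rate
(CV 0.03).  These magnitudes were chosen so that the split-half statistic
is resolvable at the 20-bout scale the analyses use — the standard error of
the evening percent-longer estimate is ~1 percentage point.  They are
smaller than the day-to-day spreads a single real participant shows
(reported second-half SDs run 2–3.5 min); consequences are discussed under
Limitations.

**Heart rate.**  Held-HR bouts record the target plus minute-wise Gaussian
jitter of SD 10 BPM (the control band); recovery decays exponentially
toward rest.  %HR_max uses the conventional 220 − age.

**Schedules.**  A program draws, per scheduled day, an adherence Bernoulli
(default 0.6) and a session window (afternoon 13:00–16:30 or evening
18:00–21:30); explicit skip-day lists override adherence for printed
schedules.  Per-bout randomness derives from a CRC-32 hash of
(master seed, participant, date), making cohorts reproducible while bouts
stay independent.

## Segmentation and fatigue detection

Phases are assigned from the smoothed trace slope with a tolerance of
0.5 °C/min (high mode) or 0.05 (low mode): rise above, plateau within,
decline below; everything after exercise end (metadata, or the steepest
sustained slope drop when absent) is recovery.  Boundaries are reported at
1-min resolution; a trace that never rises above tolerance is returned
flagged degenerate.  Note that the visible plateau end lags the latent
work-rate onset by the thermal lag plus the tolerance band (≈3–4 min at
high sensitivity); recovering the onset itself is the detector's job.

The fatigue criterion is joint: HR is *steady* iff a Theil–Sen fit over the
exercise portion drifts ≤ 15 BPM in total; LWO is *steady* iff the
estimated work rate never stays below (1 − 0.10)× its plateau median for
3 consecutive minutes.  A confirmed violation necessarily trails the true
inflection (the signal must cross the tolerance band first), so the
reported onset is the breakpoint of a two-segment constant→linear
least-squares fit, constrained to precede the confirmed violation; the
scan is exhaustive over candidate breakpoints (n ≤ 121 samples).  The
first samples of the work-rate estimate are excluded (forced Δ(0) = 0 plus
filter edge).  When both mechanisms are violated, the signal deviating by
more standard scores wins (configurable to earliest-onset).  With one
signal missing the assessment is flagged partial.

Against planted ground truth the detector recovers HR-130 onsets within
±2 min in 50/50 seeded replicates at default noise, and classifies the
constant-power bout as HR-rise fatigue with mean onset error under 2 min.

## Dosimetry

The personalized daily dose is the Δt° reached at minute 30 of a
low-sensitivity, fatigue-free, ≥30-minute moderate bout, rounded to 0.1 °C
(display rounding to whole °C, as in the 10 °C home prescription, is a
flag).  Calibration is refused otherwise; in the simulated protocol a
refused session is simply repeated on another day.  Threshold crossings are
linearly interpolated between minute samples and reported to 0.1 min,
avoiding ±1 min quantisation bias; notifications are logged events stamped
`start + t_full`, one per session by construction.  Continuous multi-day
traces are split into per-session zeroed traces at gaps where the device
cooled below 0.5 °C for ≥ 60 min.  Dose fractions are durations relative to
the 30-minute reference, valid under the low-mode linearity precondition.

## Fatigability statistics

For each completed dose event, `t_first = t_half` and
`t_second = t_full − t_half`; their sum is the total exactly.  Events group
by start time against a 17:00 cutoff (morning folds into afternoon).  The
report compares t_second and t_total between groups and t_first vs t_second
within each group — Welch's unequal-variance t test by default, a
label-permutation test (2000 resamples) as the alternative — marking
significance at 0.05 with no multiplicity correction; the number of tests
is footnoted and zero-variance comparisons are skipped with a note.
Compliance is distinct notification days per week, per participant, then
aggregated.  Incomplete events are excluded from time statistics but kept
in adherence denominators.

## Numerical and interface conventions

Traces live on the session-relative uniform 1-minute grid; absolute
date/clock live only in metadata.  CSV readers re-zero constant baseline
offsets ≤ 0.5 °C with a logged warning, interpolate single-minute gaps, and
reject larger gaps, non-monotone minutes, and out-of-range heart rates with
errors naming the row.  Writers round Δt° to 3 decimals; write→read is an
identity at that precision.  All randomness flows from explicit seeds;
identical seeds give byte-identical outputs.

## Limitations

* The generator is deliberately under-dispersed relative to a real
  participant's day-to-day spread (see Between-bout variability): passing
  tests demonstrate that the estimators recover the planted effects at the
  stated sample sizes, not that they would be equally precise on noisier
  human data.
* The thermal model ignores ambient drift, radio dropouts and absolute
  temperature; work-units are not convertible to kilocalories.
* The fatigue law is piecewise-linear with a single onset — no slow
  component, no VO₂ kinetics, no day-after strain; the diurnal effect is a
  binary afternoon/evening contrast, not a circadian curve.
* Perceived-exertion scores are generated as plausible metadata only and
  feed no computation.
* The afternoon/evening comparison inherits the usual 5% false-positive
  rate of its significance checks; a seed occasionally shows a "significant"
  afternoon difference where none is planted.
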