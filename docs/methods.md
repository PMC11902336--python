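# Methods

This note records what the package computes, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## Signal model of the generator

A synthetic subject is a hypnogram (leading/trailing wake around a cyclic
N1–N2–N3–REM sleep architecture with rare interior arousals) and a 1 Hz
SpO2 trace at a resting baseline (default 97 %). Respiratory events are a
Poisson process at `event_rate_per_hour` — which therefore *is* the
subject's true AHI up to Poisson noise — with lognormal annotated durations
(mean 21.6 s, SD 11.81 s, clipped to [10, 90] s, matching the event-length
statistics reported for large polysomnography cohorts) and overlaps thinned
out. Each event imprints a desaturation: 10 s after onset the saturation
falls linearly for 10 s to a depth drawn from [3, 10] % (apneas sample the
deeper half), holds 5 s, and recovers over 15 s. Slow baseline wander is a
one-sided sinusoid (period 1 h, default amplitude 1 %), so the signal never
exceeds the baseline and the minimum is bounded by baseline − depth −
drift. Sensor dropouts are runs of 0 with geometric duration (mean 2 s) at
`artifact_rate_per_hour`. Gaussian measurement noise is available
(`noise_sd`) but off by default, so the default conditions are
clean-signal conditions.

What the generator does **not** emulate: beat-to-beat oximeter
quantization, position-dependent artifact clusters, REM-dominant event
clustering, oximeter averaging-window distortion, or any airflow/effort
physiology. Passing tests therefore bound behavior under favorable,
well-specified conditions; they do not certify clinical performance.

## Preprocessing

Subject screening excludes a night when flagged outliers exceed 1/5 of the
signal, fewer than 3 sleep stages appear, sleep efficiency (TST / time in
bed, from the hypnogram) is below 50 %, or TST is under 5 h; all
inequalities are strict, ties pass. Cleaning clips the wake edges, mean-
decimates to 1 Hz, flags samples outside [60, 100] % or adjacent to a
first difference above 4 %/s, and interpolates flagged runs whose outlier
core (range-violating samples; a lone dropout also flags its two
delta-violating neighbours) lasts under 3 s provided every touched window
is at most 10 % flagged. Residual runs stay flagged: the windows containing
them are dropped (as is any flagged label-0 window), while the overnight
copy used for global features bridges them by interpolation — overnight
summary indices must not be dominated by dropout zeros. Windows are
half-open `[k·w, (k+1)·w)`; a window is positive when annotated event time
inside it strictly exceeds 5 s.

## Features

Per-window (14): min, mean, SD, range, min − overnight mean, fractions
below 95/90/80 %, sample entropy (m=1, r=0.25·SD), normalized permutation
entropy (order 3), max/mean absolute first difference, fraction of steps
> 3 %/s, and the fraction of the window inside an in-window desaturation
(≥ 10 consecutive seconds more than 3 % below the overnight mean).

Overnight registry (43 signal features + 4 demographics): time-domain
summaries with Px/Mx at 95/90/85 % and the delta index over 12 s interval
means; Welch PSD (512 s segments, 50 % overlap) total/band/ratio/peak in
the 0.03–0.17 Hz ventilatory band; ApEn and SampEn (m=1, r=0.25·SD,
averaged over 600 s windows — a full-night O(N²) pass is avoided and
epoch-averaged entropy is the standard estimator in oximetry work), PeEn,
LZ76 on the median-binarized signal, DFA slope over 10–300 s scales, and
CTM (ρ=1) on second differences; PRSA (decrease anchors, T=10 s) central
capacity, amplitude difference and three slopes; desaturation events
(≥ 3 % below a trailing 120 s maximum baseline, ≥ 10 s) summarized by
count/h (ODI3) and length/depth/slope/area/gap moments; hypoxic burden
(fraction of time in desaturation, desaturation area per hour, CT90,
area below 90 % per hour). The desaturation baseline convention (running
120 s maximum) is the one free choice and is pinned by unit tests.

## Broad learning system

Inputs are z-scored per column (zero-variance guard; standardized values
clipped at |z| ≤ 8 — an out-of-distribution subject, e.g. an event-free
night scored against apneic training nights, otherwise acquires unbounded
leverage and the random-feature ridge extrapolates absurd AHIs; the clip is
inactive in distribution). Feature nodes are grouped random linear maps
drawn per input column from seeds spawned off the config seed (10 groups ×
10 nodes by default); enhancement nodes apply tanh to an orthonormalized
random projection scaled so its pre-activation maximum is 0.8 (100 nodes);
the output layer solves the ridge normal equations exactly (λ = 2⁻¹⁰ by
default, as in the BLS literature). Incremental features join as a
standardized identity-mapped group that bypasses the enhancement bank, so
a zero increment provably changes nothing and the incremental refit equals
a from-scratch fit on the concatenated design; a block-inverse (Greville
style) update is provided and agrees with the re-solve to 1e−8.

The subject-level regressors (global-feature AHI, detection-statistics
AHI, fused output) use λ = 1: they see tens of rows against a ~200-column
random design, and the desk-scale ridge keeps them from interpolating.
Regressed log-AHI is capped at ln(301) before the inverse transform
`Y = exp(Y′) − 1`, which is floored at 0.

## Fusion and correction

The detection-statistics features are the predicted-event time fraction,
run-length mean/SD, fractions of windows with P̂₀ > 0.5 and < 0.3, and the
mean probability over predicted events and over multi-window runs. The
correction triggers only when the two AHI estimates differ by strictly
more than 10 events/h. The corrected count is `Evend = round(|ΔAHI|·60)`
by default — the printed event-count form, kept verbatim for
reproducibility even though it is dimensionally an event count only for a
60-minute night; `evend_mode="hours"` selects the coherent `|ΔAHI|·T/60`.
The ⌈0.1N⌉ most confident windows are skipped and the next `Evend` in
descending probability order are scaled by `(1 ± v)`,
`v = 0.5·Evend·(60/T)·(i/N)` with the temporal position `i`; results are
clipped to [0, 1]. In practice `v` exceeds 1 for most selected windows, so
a triggered correction saturates them — a property of the printed
formulas, not of this implementation.

On clean synthetic cohorts the two AHI estimates almost always agree
within the trigger, so corrections fire for at most a few subjects per
cohort, and those firings trace to subject-level regression error rather
than detection error; the fusion then leaves detection essentially
unchanged (recall within half a percent of the ablated arm) while the
global branch roughly halves the AHI RMSE. The correction earns its keep
in regimes where window detection is substantially error-prone, which the
clean generator deliberately is not. An inner cross-fitted variant of the
detection-statistics regressor was evaluated and discarded: half-size
inner folds under-train the detector and shift the statistics the other
way.

## Evaluation protocol and problem sizes

Cross-validation is always split by subject (seeded shuffle, round-robin
folds; samples of one night never cross folds). Reported metrics: pooled
window-level ACC/MF1/κ/recall/precision; subject-level MAE/RMSE, R² in
both the regression-sum-of-squares form (`r2_paper`, which can exceed 1)
and the conventional `1 − SSres/SStot`, and ICC(2,1) from the explicit
two-way ANOVA mean squares (cross-checked against an independent
implementation to 1e−10); 4-class severity and the 5/15/30 binaries with
left-closed bins (AHI exactly at a threshold takes the higher class).

The bundled experiments use 80-subject cohorts of 6 h nights (~57 000
windows per cohort, 5-fold CV) as the standard problem size, and smaller
cohorts in unit tests; a full cohort run takes tens of seconds on one CPU.

## Known limitations

- The clean-signal generator makes window detection easier than clinical
  oximetry; recall ~0.75 here reflects label/physiology lag at window
  boundaries (desaturations trail their events by ~10 s), not sensor noise.
- The verbatim corrected-count formula saturates probabilities when it
  fires; users wanting a graded correction should set
  `evend_mode="hours"`.
- Overnight entropies are 600 s epoch averages, not full-night values.
- EDF/annotation-XML ingestion is limited to single-channel reads via
  optional helpers; the canonical input is the CSV/TSV/JSON fixture
  triplet.
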