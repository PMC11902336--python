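# sasbls

Sleep-apnea event detection and apnea–hypopnea-index (AHI) prediction from
a single overnight SpO2 channel, built on broad learning systems (BLS).

Sleep Apnea Syndrome is scored clinically from polysomnography: technicians
mark every apnea/hypopnea event and summarize a night by the AHI (events
per hour of sleep, with severity grades none/mild/moderate/severe at the 5,
15 and 30 cut-offs). Pulse oximetry is the cheapest channel that carries an
event signature — each obstruction leaves a transient oxygen desaturation —
so SpO2-only screening is attractive for home sleep testing. The catch is
that window-by-window classifiers ignore what the whole night says about a
patient, while whole-night AHI regressors ignore the event-level detail
clinicians still need.

`sasbls` implements a dual-branch model that does both tasks at once and
lets them correct each other:

1. **Detection branch.** The night is cleaned (wake-edge clipping, 1 Hz
   resampling, delta-filter artifact interpolation) and cut into 30 s
   windows, labeled positive when more than 5 s of an annotated event falls
   inside. A BLS — random mapped-feature groups, tanh enhancement nodes,
   and a ridge-regularized closed-form output layer
   `W = (AᵀA + λI)⁻¹AᵀY` — classifies per-window feature vectors into an
   initial probability sequence P̂₀.
2. **AHI branch.** 39 overnight features (saturation statistics, 0.03–0.17
   Hz spectral power, entropy/complexity measures, phase-rectified signal
   averaging, desaturation-event and hypoxic-burden indices) plus
   demographics feed a BLS regressor trained on log-transformed labels
   `Y′ = ln(Y + 1)`, giving the global estimate AHÎ_g.
3. **Fusion (SDFFU).** A second regressor predicts AHÎ_s from statistics of
   the detection sequence itself. When |AHÎ_g − AHÎ_s| > 10 events/h the
   probability sequence is scaled toward the global estimate with a
   position-dependent coefficient `v = 0.5·Evend·(60/T)·(i/N)`, clipped to
   [0, 1]. The corrected sequence is expanded into 5-window context blocks,
   re-classified by confidence-gated context models, and fused with the raw
   window features in an incremental BLS whose closed-form refit is exact.
   The final AHI output fuses the counted detection AHI back into the
   global regressor the same way.

Everything is evaluated with subject-wise k-fold cross-validation: ACC,
macro-F1, Cohen's κ, recall/precision for detection; MAE, RMSE, R² and
ICC(2,1) (two-way random effects, absolute agreement) for AHI; 4-class and
binary severity summaries.

Restricted-access clinical recordings are not required anywhere: the
`synth` module generates overnight recordings with a known event process
(Poisson onsets at the target AHI, lognormal 21.6 ± 11.81 s durations,
piecewise-linear desaturations, baseline drift, sensor dropouts), so the
whole pipeline is testable offline against exact ground truth.

## Worked example

```python
from sasbls import generate_cohort, run_pipeline, RunConfig

recs = generate_cohort(20, seed=42)          # 20 synthetic subjects
res = run_pipeline(recs, RunConfig(seed=0))  # 5-fold CV by subject
print(res.report.to_text())
```

prints

```
subjects=20  samples=14190
SAS detection   acc=0.8328  mf1=0.7698  kappa=0.5414  recall=0.5830  precision=0.7327
AHI regression  icc=0.7895  r2=0.3620  mae=5.9867  rmse=7.4529
SAS severity    acc=0.5000  mf1=0.5225  kappa=0.2754  recall=0.6042  specificity=0.8177
binary @ 5    acc=0.9500  mf1=0.8857  kappa=0.7727  recall=0.9444  specificity=1.0000
binary @ 15   acc=0.9000  mf1=0.8667  kappa=0.7368  recall=0.8750  specificity=1.0000
binary @ 30   acc=0.6500  mf1=0.5611  kappa=0.1463  recall=0.5000  specificity=0.6875
```

83 % of the ~14k held-out windows are classified correctly and the per-subject
AHI estimates agree with the truth at ICC 0.79 — modest numbers at this
cohort size; an 80-subject cohort reaches window accuracy ≈ 0.92 and AHI
ICC ≈ 0.99 (see below). `res.subjects` holds the per-subject table:

```
subject_id  ahi_true  ahi_hat severity
     S0000     29.17    22.38 moderate
     S0001     29.50    30.80   severe
```

The same flows are available from the shell:

```sh
sasbls simulate data/ --n-subjects 20 --seed 42
sasbls evaluate data/ --out-dir run/ --seed 0
sasbls sweep-window data/ --windows 10,30,60,120
sasbls ablate data/ --seed 0
```

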