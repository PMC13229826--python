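# Methods

This note records the models, conventions and numerical choices behind
`hrvpoincare`, and what the synthetic validation does and does not
establish.

## Signal model of the synthetic tachogram

`generate_rri` composes each interval additively:

    RR_i = mean_rr + LF + HF + trend + jitter

* **LF**: `lf_amp · sin(2π·0.10·t_i)` — baroreflex-band oscillation.
* **HF**: `hf_amp · sin(φ_i + s·sin φ_i)`, `φ_i = 2π·0.25·t_i` — the
  respiratory component, phase-modulated by the asymmetry dial `s`
  (`asym_skew`). For `s > 0` the waveform decelerates gradually and
  accelerates briskly, the pattern behind heart-rate asymmetry in
  vagally mediated rhythms.
* **trend**: `trend_amp · sin(2π·0.01·t_i)` — non-stationary drift below
  the LF band, the component the detrending stage exists to remove.
* **jitter**: an AR(1) process (coefficient 0.9) driven by zero-mean
  two-sided-exponential innovations with unequal rates: positive steps
  (decelerations) occur with probability (1+s)/2 at proportionally smaller
  scale, so the mean stays zero while the *frequency* of decelerations
  rises with `s`.

Nominal beat times `t_i = i·mean_rr` drive the oscillator phases.

Why two asymmetry mechanisms on one dial: innovation skew alone cannot move
the distance/angle/area indices, because for any zero-mean increment law the
expected up-distance and down-distance sums are equal (and realised sums
telescope to the endpoint difference). The frequency bias moves the
count-based Porta index; the waveform bias moves the slope and area indices
of the detrended residual; the Guzik index stays near balance under both —
the same dissociation pattern (PI, SI, AI responsive; GI ≈ 0 after
detrending) seen in short resting recordings.

Defaults (`mean_rr` 0.82 s, 366 beats ≈ 5 min, `lf_amp` 0.013 s, `hf_amp`
0.015 s, `trend_amp` 0.025 s, `jitter_sd` 0.012 s) were calibrated once to a
resting cohort at ~73 bpm: they yield SDNN ≈ 25 ms, RMSSD ≈ 15 ms, LF ≈ 118
ms², HF ≈ 124 ms², LF/HF ≈ 0.95, ApEn ≈ 1.2, SD1 ≈ 10 ms, SD2 ≈ 33 ms,
GDR ≈ 0.018, GDE ≈ 5.86 — the orders of magnitude of middle-aged adults at
rest.

**What the generator does not emulate**: genuine respiratory coupling
(amplitude/frequency modulation by tidal volume), 1/f background, circadian
structure, ectopy beyond the stylised premature/compensatory pair, or any
physiologic correlation between covariates and rhythm (covariates influence
the signal only through the optional `confound_strength` dial). Passing
tests on this generator therefore validates the *algorithms* — detection
accuracy, filter behaviour, metric definitions, statistical calibration —
not clinical effect sizes on real recordings.

Cohort generation: the positive group's `asym_skew` is lowered by
`ai_effect` (less spatial asymmetry) and its broadband jitter shrunk by
`complexity_effect`, with a 5%·effect mean-RR lengthening at fixed recording
duration (fewer Poincaré points is what principally lowers grid occupancy
and its log-count-dominated entropy). Covariates are drawn per group from a
fixed demographic model (age ≈ 51.6±10.2 vs 48.9±9.7 y; menopause 55.6% vs
32.9%; PR 48.6% vs 63.2%; Ki-67 78.7% vs 52.6%). `generate_metric_cohort`
draws standardized metric *values* directly (unit-variance noise plus a
specified group shift, or a covariate-driven term with no group effect) and
exists for high-replicate calibration of the statistics layer.

## ECG synthesis and R-peak detection

Synthetic ECG renders a Ricker-wavelet QRS (~80 ms wide) at each beat time,
an optional Gaussian T wave 250 ms after each R, a sub-0.5 Hz baseline
wander sinusoid and white noise; true R indices are returned for audit.

The detector follows the classic adaptive chain. Choices where only the
structure, not the constants, is canonical:

* Butterworth order 3, applied forward–backward (zero-phase), so the
  integrated energy signal stays aligned with the bandpassed trace used for
  apex refinement.
* Five-point derivative kernel `(2, 1, 0, −1, −2)/8 · fs` with its 2-sample
  group delay compensated; edges are replicated so a constant trace maps to
  an exactly zero transform.
* Running signal/noise peak levels updated with weights 1/8 and 7/8;
  threshold = noise + 0.25·(signal − noise); search-back at half threshold
  when no beat appears within 1.66× the running RR mean (mean of the last 8
  accepted intervals).
* T-wave rule: a candidate within 0.36 s of the last accepted peak is
  rejected when its maximal absolute bandpassed slope is below 50% of the
  previous peak's.
* Apex refinement = argmax of |bandpassed signal| within ±150 ms; a final
  pass enforces the 0.2 s refractory period, keeping the larger apex.

All thresholds derive from the signal itself, so detection is invariant to
global amplitude scaling (asserted by test).

## Quality control

Two rules, in order: intervals outside [0.3, 2.0] s are discarded
unconditionally; then, walking the spliced series, any interval whose
relative change against the **last accepted** interval exceeds 20% is
discarded. An ectopic premature/compensatory pair (×0.6, ×1.4) trips the
rule on both members. Immediate neighbours of removed clusters are flagged
(`cluster_flag`) in the QC report but kept; `neighbor_margin` widens removal
when a more aggressive policy is wanted. Referencing the last accepted
interval (rather than the immediate predecessor) keeps the filter from
cascading through the healthy beats that flank an artifact, and makes it
idempotent. A recording losing >50% of intervals raises an "unusable
recording" error; the pipeline converts this into a subject exclusion with a
reason code.

## Detrending and the detrended-metric convention

Smoothness priors with difference order 2 and λ = 500; the regulariser
enters as λ², and the sparse pentadiagonal system is solved exactly
(N ≈ 400). Straight lines lie in the penalty null space and pass to the
trend exactly; the operator is linear; trend + residual reconstructs the
input to machine precision (all asserted).

Detrended-condition metrics are computed on the **zero-mean residual**, with
the spectral resampling clocked by the cleaned series' cumulative beat
times. Translation along the identity line leaves every metric except SI
and AI unchanged (SDNN/RMSSD/SD1/SD2/entropy/PI/GI are
translation-invariant; band powers see only deviations). For SI/AI the
convention matters: restoring the mean places all points near (m, m), where
the sector-area weight degenerates to a constant times the vertical
distance, collapsing AI onto GI and freezing both near zero. On the
zero-mean residual the radii and phase angles genuinely vary, producing the
characteristic ~10× raw-to-detrended magnitude jump in SI/AI and making AI
responsive to waveform asymmetry. `mean_restored=True` remains available.

## Metric conventions

* Variances use ddof = 1 throughout; SD1 = SDSD/√2 and
  SD1² + SD2² = 2·SDNN² hold exactly and are asserted.
* Asymmetry indices exclude identity-line points from numerator and
  denominator; a series with no off-line points returns flagged NaNs.
  GI uses linear vertical distances |y − x| by default (`gi_mode="squared"`
  gives the classic squared variant). The distance is measured parallel to
  the y-axis; a perpendicular measure differs by √2, which cancels in the
  ratio.
* Grid metrics use a square bounding box over the combined coordinate
  range, half-open cells with the top/right edge assigned to the last cell,
  natural-log entropy, and an equal-weight average over n = 100…200.
  Degenerate (zero-range) input returns 1/n² occupancy and zero entropy by
  convention, flagged.
* Entropy: ApEn includes self-matches over the full template set per
  dimension; SampEn counts ordered template pairs over the shared N − m
  templates at dimensions m and m+1, so perfectly regular series give
  exactly 0; A = 0 returns +inf with the caller expected to flag, not
  fail. r = 0.2 × the sample SD of the analysed series.
* Welch band powers: cubic-spline resampling at 4 Hz (linear available),
  per-segment mean removal only (trend handling belongs to the detrending
  stage), trapezoidal integration, the shared 0.15 Hz edge assigned to HF.

## Statistics

* Normality gate: Shapiro–Wilk per group at α = 0.05; Student's t (equal
  variances) only when **both** groups pass — the conservative conjunction.
* Cohen's d always uses the pooled sample SD of the raw values, even when
  the gate selected Mann–Whitney; its 95% CI uses the large-sample SE
  √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))), validated by coverage simulation.
* ANCOVA: OLS with group coded 0/1; the adjusted p is the group
  coefficient's t-test (equivalent to Type III for a two-level factor);
  partial η² = SS_group/(SS_group + SS_residual), equal to the squared
  partial correlation (asserted against an independent residualisation).
  Collinear covariates raise an error naming the offending columns.
* ROC: rank (Mann–Whitney) AUC with midrank tie correction;
  auto-orientation records which direction was used. Cross-validation is
  stratified 10-fold with a per-fold univariable logistic score; the CV-AUC
  is the **mean of per-fold AUCs** — a pooled-score AUC is pessimistically
  biased under weak signal because fold-specific score shifts anti-correlate
  with held-out labels, and the fold average is exactly calibrated at 0.5
  under permuted labels (asserted). Sensitivity/specificity are
  whole-cohort counts at the Youden threshold of the pooled validation
  scores.
* No multiple-testing correction is applied anywhere; the metric panel is
  geometrically inter-correlated and the analysis is exploratory. Report
  metadata states this explicitly.
* The ANCOVA stage receives exactly the metrics whose unadjusted p falls
  below α — the selection is part of the report contract.

## Problem sizes used in validation

The test suite and acceptance script run entirely on synthetic data at
deliberately chosen sizes: 20 detection seeds × 5-minute ECGs at 400 Hz;
50 random series (length 20–100) for brute-force oracle equivalence;
500 replicates for null calibration and permuted-label CV; 200 replicates
for effect recovery (d = 0.4 at n = 142/76, compared against noncentral-t
analytic power) and for the confounding contrast; one full 218-subject
cohort run twice to assert byte-identical outputs. These sizes keep
Monte-Carlo standard errors comfortably inside the asserted tolerances.

## Known limitations

* The detector is tuned for clean resting single-lead recordings; it is not
  validated for arrhythmia, severe noise, or morphology changes (its
  T-wave rule assumes a dominant R amplitude).
* The QC filter removes, never interpolates; downstream spectra treat the
  spliced series as gapless, which slightly blurs frequencies when many
  beats are removed.
* Grid metrics at n = 100–200 on ~360 beats operate near the one-point-per-
  cell regime, so GDE tracks ln(beat count) closely; between-group GDE
  differences are dominated by beat-count differences, not fine spatial
  structure.
* The synthetic cohort's effect dials are not metric-selective: lowering
  `asym_skew` also perturbs waveform regularity (entropy). Real group
  contrasts will likewise co-move correlated metrics; the statistics layer
  deliberately reports uncorrected per-metric results.
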