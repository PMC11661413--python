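# Methods

`ppgarr` implements a complete, desk-scale pipeline for three-class
cardiac rhythm classification (normal sinus rhythm, atrial fibrillation,
premature atrial/ventricular contractions) from 30-second, 50 Hz wrist
photoplethysmography with co-recorded accelerometer magnitude.  Every
stage — synthetic data generation, preprocessing, rule-based
adjudication, the recurrent classifier, subject-wise cross-validation,
and the metric panel — runs on a single CPU core on synthetic data; no
downloads are required.

## The classification problem

Paroxysmal AF produces an irregularly irregular pulse; premature beats
produce isolated short-coupled pulses followed by compensatory pauses.
Both are visible in the inter-beat dynamics of wrist PPG, but so is
motion artifact, which corrupts the waveform and fakes exactly the
irregularity that arrhythmias produce.  The pipeline therefore feeds the
classifier four aligned channels per segment, each normalized to [0, 1]:

| channel | construction | normalization |
|---|---|---|
| PPG | 6th-order Butterworth band-pass 0.5–20 Hz, zero-phase | per-segment min–max |
| HR | rectangular (step) interpolation of 60/IBI from detected pulse peaks | fixed range [30, 220] BPM |
| ACC | accelerometer magnitude | clipped to [0, 20] m/s², divided by 20 |
| magHR | same rectangular HR | per-segment min–max ("magnified") |

Rectangular rather than linear HR interpolation is deliberate: a step
series preserves the abruptness of premature-beat HR excursions that
linear interpolation smears.  The fixed-range HR channel keeps rapid
ventricular response on scale; the magnified channel preserves small
local dynamics (e.g. the two-level zig-zag of bigeminy) that the fixed
range compresses to a near-flat line.  The ACC channel lets the model
learn that HR excursions coincident with elevated acceleration are
artifact, not arrhythmia.

Constant-input min–max normalization returns 0.5 everywhere (the least
informative value); out-of-range HR and ACC are clipped, not rescaled,
since the stated ranges are physiological bounds.  Missing ACC is
represented by the constant 9.8 m/s² (≙ 0.49 after normalization);
tri-axial ACC is reduced to its Euclidean magnitude, and gravitational
units are converted by ×9.8.  External recordings at higher rates are
resampled to 50 Hz with polyphase anti-aliasing filtering.

## Segment adjudication rules

Machine-readable beat annotations are labeled by three rules applied in
order, with instantaneous HR defined as 60/IBI:

1. **AF** — beat-to-beat irregularity (|ΔHR| ≥ 10 BPM) spans the whole
   segment.  When ground truth is absent this is operationalized as
   "every non-overlapping 5-s window contains at least one ≥ 10 BPM
   change"; the ECG-based missing-P-wave criterion used in clinical
   adjudication is not representable from PPG, so synthetic ground
   truth carries the AF span flag directly.
2. **PAC/PVC** — a non-AF segment with ≥ 3 premature beats, a premature
   beat being one whose instantaneous HR differs from the preceding
   interval's by ≥ 10 BPM (a sinus beat typically varies by less).
3. **NSR** — everything else; up to two premature beats are tolerated.

A segment is usable when it carries ≤ 5.0 s of motion artifact.  The
≥ 10 BPM comparisons use a 10⁻⁹ BPM absolute tolerance so that HR values
exact in BPM but inexact after the 60/IBI float round trip remain on the
inclusive side of the boundary.

## Synthetic data generator

The generator emulates the statistical structure of real smartwatch
monitoring data, not its waveform physiology.  What it reproduces:

- **NSR**: a reflected random walk on HR (steps ≤ 3 BPM, band ±8 BPM
  around the subject mean) keeps every beat-to-beat change below
  10 BPM.  A configurable fraction of NSR segments carries one late
  premature beat, placed so that at most two beats are flagged and the
  segment stays NSR under the rules above.
- **AF**: i.i.d. log-normal instantaneous HR with coefficient of
  variation 0.2 (no serial correlation), rejection-sampled until every
  5-s window contains a ≥ 10 BPM change.  The log-normal is placed on
  HR rather than on RR so the population mean of instantaneous HR
  equals the requested mean exactly; a log-normal on RR would bias it
  upward by (1 + CV²).
- **PAC/PVC**: isolated, bigeminy, or trigeminy patterns.  A premature
  event advances one beat to `coupling` (default 0.65) × the preceding
  RR; the next beat keeps its grid position, which realizes a fully
  compensatory pause of (2 − coupling) × RR and the canonical zig-zag
  rectangular-HR shape.
- **PPG waveform**: one pulse template per beat — an asymmetric
  systolic bell (rise σ 0.055 s, fall σ 0.095 s) plus a dicrotic
  sub-wave at +0.25 s with 0.40 relative amplitude — with ±5% amplitude
  jitter, baseline wander (0.15 amplitude, 0.15–0.35 Hz) and additive
  white noise (σ 0.03).  Premature pulses are attenuated by their
  relative filling time, mimicking reduced stroke volume.
- **Motion artifact**: Poisson-count bursts per segment whose total
  duration is fixed (default 3.0 s, within the usability gate) and
  snapped to the sample grid; inside a burst the PPG is gain-distorted
  and overlaid with band-limited (0.5–10 Hz) noise at 3× the clean RMS,
  while the ACC magnitude rises from its 9.8 m/s² rest value by several
  m/s².  Outside bursts the samples are bit-identical to the clean
  trace.
- **Population structure**: subjects are NSR-only, AF, or PAC/PVC
  carriers; per-subject rhythm burden is Beta-distributed around the
  configured mean, so some arrhythmia-labeled subjects contribute few
  or no arrhythmic segments.  The default composition (16 NSR-only, 7
  AF, 7 PAC/PVC subjects × 12 segments) yields roughly a 10:2:1
  NSR:AF:PAC/PVC segment mix, mirroring the strong class imbalance of
  real monitoring data at a desk-friendly size.

All randomness flows from a single seeded generator, so a configuration
reproduces a byte-identical dataset.  What the generator does *not*
emulate: real PPG morphology classes (respiratory modulation, notch
variation, site- and sensor-dependent waveform shape), ECG-visible
features (P-waves), serially correlated AF dynamics, and realistic
artifact morphology.  Passing tests on this data therefore demonstrate
that the pipeline's machinery — preprocessing fidelity, leakage-free
protocol, trainability, metric correctness — works end to end; they do
not certify clinical performance on real recordings.

## Pulse-peak detection

Peaks are detected on the filtered PPG by an envelope-guided search: a
moving-RMS envelope (0.3 s window) sets an adaptive threshold at 0.4 ×
envelope, floored at 0.4 × 0.6 × segment RMS so diastolic troughs cannot
promote baseline noise; local maxima above threshold are kept under a
60/220 s refractory period; a residual candidate within 0.35 s of the
last accepted peak at < 0.55 of its height is discarded as a dicrotic
wave.  On clean synthetic segments this recovers ≥ 95% of beats to
within ±1 per segment across NSR, AF, and bigeminy.  The detector is a
self-contained approximation of envelope-based PPG beat detectors; any
detector meeting the same contract (strictly increasing times,
refractory period, one peak per pulse) can be substituted.

## Classifier

For an (L, d) input (L = 1,500 samples, d ≤ 4 channels):

1. 1-D convolution d → 4d, kernel 5, stride 1, padding 2 — a linear
   embedding that preserves sequence length;
2. bidirectional GRU, 128 units per direction (two bias vectors per
   gate), concatenated to (L, 256);
3. batch normalization over the 256 features, statistics pooled over
   batch and time; then 20% inverted dropout (training only);
4. per-time-step dense layer 256 → 3;
5. aggregation of the (L, 3) per-step logits to one segment logit
   vector — mean over time by default (`last_step` and `max_logits`
   are selectable for sensitivity analysis) — followed by softmax.

Classes are coded 0 = NSR, 1 = AF, 2 = PAC/PVC.  The trainable
parameter count is

    (20d² + 4d) + 2·3·(128·4d + 128² + 2·128) + 2·256 + (256·3 + 3)

= 113,747 at d = 4, growing by 20(2d+1) + 4 + 3,072 per added channel;
batch-norm running statistics are buffers and are not counted.

The implementation is self-contained NumPy/Numba: the recurrence runs in
jitted single-precision kernels (branch-free inner loops with a
polynomial exp accurate to ~2×10⁻⁶ relative), and backpropagation
through time is derived and implemented by hand.  The forward kernel is
verified against a float64 reference recurrence and the full gradient
against central finite differences in the test suite.

## Training protocol

- Subject-wise two-fold cross-validation: subjects with AF and with
  PAC/PVC are split evenly (±1) between two folds; NSR-only subjects
  form a held-out test pool.  Within a fold, subjects are partitioned
  80/10/10 into train/validation/subject-dependent test, stratified on
  rhythm type; at small cohort sizes the stratification dominates the
  exact percentages — the validation pool always receives one AF and
  one PAC/PVC subject where available, since a single-subject
  validation pool that happens to miss a class makes the
  model-selection loss blind to it.  Each fold's model is tested on the
  entire other fold plus the NSR-only pool, so every test prediction
  comes from a model that never saw that subject.
- Class balancing: training and validation sets are upsampled by
  duplication to the NSR segment count; test sets are never modified.
- Optimization: cross-entropy on mean-pooled logits, Adam (defaults:
  step 10⁻³, moment decays 0.9/0.999), batch 32, up to 200 epochs,
  early stopping after 40 epochs without strict validation-loss
  improvement, checkpoint at minimum validation loss.  A global
  gradient-norm clip (default 5.0) guards the 1,500-step BPTT against
  rare exploding gradients; it can be disabled.
- Epoch-wise validation losses are computed with the statistics of the
  evaluated batches (dropout off, running averages untouched), because
  the exponentially averaged BN statistics trail the weights when an
  epoch is only a few optimizer steps, which would reduce the selection
  signal to noise.
- Batch-norm re-estimation: after weight selection the running BN
  statistics are replaced by exact statistics computed in one
  frozen-weight pass over the training data.  At full scale the
  exponential running average converges by itself; at desk scale (tens
  of optimizer steps) it trails the weights badly enough to distort
  evaluation-mode predictions, so the checkpoint always carries exact
  statistics.

## Evaluation panel

3×3 confusion matrices (rows true, columns predicted; argmax decisions
with ties toward the lower class index); per-class one-vs-rest
sensitivity, specificity, precision, NPV, and accuracy, with
zero-denominator metrics reported as undefined (NaN) rather than 0; the
two fold matrices are summed entrywise and the resulting metric values
averaged, unweighted, with the NSR-pool metrics wherever both are
defined (all three tables are also returned separately, so either
reading of "averaging" is recoverable).  AUROC uses the rank statistic
(Mann–Whitney, ties one half), which equals trapezoidal ROC
integration; macro-AUROC is the unweighted mean of the three
one-vs-rest areas, micro-AUROC the area over the flattened
indicator/score pairs.  A binary AF/non-AF collapse folds PAC/PVC into
NSR and reports the 2×2 panel plus the AUROC of the AF probability
column.

One caveat specific to the two-fold protocol: probabilities emitted by
the two independently trained fold models are not on a common scale, so
an AUROC over their pooled predictions confounds each model's ranking
with the calibration mismatch between them.  Confusion-matrix metrics
are immune (argmax decisions), but ROC analysis is not; the reference
studies therefore compute macro-AUROC within each model's own
subject-independent test pool and average the two values — mirroring
how the protocol averages fold metrics — and report the
pooled-prediction value alongside for reference.

## Desk-scale reference studies

Two canonical studies in `ppgarr.experiments` exercise the full
pipeline at sizes one CPU core completes in minutes:

- **Two-fold learnability** (`two_fold_study`): 30 subjects (10
  NSR-only, 10 AF, 10 PAC/PVC) × 10 segments = 300 segments, ~10:2:1
  class mix, light artifacts; four-channel model, full two-fold protocol,
  repeated over 3 training seeds, scored by the per-model macro-AUROC
  described above.  The short schedule uses Adam step 10⁻² for at most
  20 epochs — an epoch is only a handful of mini-batches at this scale,
  and pilot runs showed that smaller steps cannot clear the initial
  loss plateau within tens of optimizer steps while larger or decayed
  schedules destabilized training.
- **Multimodal benefit** (`multimodal_benefit_study`): an
  artifact-heavy suite (14 subjects × 6 segments, most segments
  carrying a 4-s burst) in which NSR segments show artifact-coincident
  HR jumps with elevated ACC.  The four-channel model and a PPG-only
  model are trained identically (3 seeds); the quantity compared is how
  many held-out artifact-carrying NSR segments each calls PAC/PVC.
  The expectation is directional: the ACC-aware model should confuse
  fewer.

## Numerical choices and limitations

- Single precision throughout the network; the fast exp introduces
  ≤ 2×10⁻⁶ relative error, negligible against float32 rounding.
- Zero-phase (forward-backward) filtering doubles the effective filter
  attenuation; the contract is band selection, not exact gain.
- The conv embedding is linear (no activation); batch normalization
  pools statistics over batch and time; both are the simplest readings
  of the architecture's stated layer order.
- The windowed AF-span test is a stated approximation of "irregularity
  spanning the segment"; bigeminy also satisfies it, so ground-truth
  span flags (not the windowed test) adjudicate synthetic AF.
- Fold assignment with very few subjects keeps at least one validation
  and one test subject per fold; pools too small to contain all three
  classes fall back to unbalanced training with a warning.
- Printed headline metrics from full-scale real-data studies (e.g.
  PAC/PVC sensitivity above 80% on ~167k segments) are out of reach at
  desk scale and are not targeted by the test suite; the studies above
  check learnability and directional properties instead.
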