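# Methods

This note documents the models, parameters, and numerical choices behind
`ppgbp`, in the order the pipeline runs them.

## Synthetic record generator

The generator (`ppgbp.synthetic`) emulates paired PPG/ABP acquisition at
125 Hz.  One record is a sequence of beats; per beat:

- **Heart rate** follows a multiplicative jitter walk,
  `hr ← clip(hr·(1 + U(−1,1)·hr_variability), hr_range)`, default range
  55–95 bpm with 2% per-beat jitter.
- **Pressures** follow independent bounded random walks with reflecting
  boundaries: SBP in 90–180 mmHg, DBP in 45–80 mmHg, step ≤ 2 mmHg/beat.
  The ranges are disjoint (SBP lower bound > DBP upper bound) so every beat
  satisfies DBP < SBP.
- **Pulse shape** is the sum of a systolic Gaussian (center at 32% of the
  cycle) and a delayed dicrotic Gaussian (center at 60%), endpoint-detrended
  to start and end at zero and rescaled so the maximum equals the requested
  systolic amplitude.  A two-Gaussian pulse is the simplest shape with one
  dominant systolic peak and a dicrotic component — all that peak detection
  and two-cycle segmentation require.
- **ABP** is the pulse affinely scaled to [DBP, SBP], so the per-beat ABP
  maximum/minimum *are* the labels.
- **PPG morphology encodes the pressures linearly**: systolic width
  fraction w = 0.095 + 0.0005·(SBP − 135) and relative dicrotic amplitude
  d = 0.30 + 0.006·(DBP − 65).  The constants are module-level and the
  inverse map is exported (`morphology_to_bp`), giving recovery tests a
  closed-form target.  Width-as-a-fraction survives spline resampling and
  relative amplitude survives z-scoring, so the information reaches the
  models.

Baseline drift (0.1 Hz sinusoid, inside the A8 band so denoising removes
it), Gaussian noise (PPG sd 0.02 signal units; ABP sd 0.3 mmHg), and
optional corruption are applied **after** ground truth is recorded.
Flatline corruption replaces a random 1–3 s PPG window with a constant;
flat-peak corruption clips a window at its 90th percentile.  Corruption and
drift affect only the PPG channel so the ABP-derived labels stay
meaningful.

What the generator does **not** emulate: pulse-transit-time physiology,
motion artifacts with structure, inter-subject morphology diversity beyond
the linear coupling, sensor quantization.  Passing tests therefore show the
pipeline's machinery is correct and that the models can recover a
morphology→pressure mapping when one exists; they say nothing about
accuracy on real ICU waveforms.

## Preprocessing

- **QC**: flatlines are maximal runs with |first difference| ≤ tolerance
  (default 0) lasting ≥ 1 s; flat peaks are plateaus of ≥ 3 identical
  samples forming a local maximum (the signature of clipping; a plateau
  rule tied to the global running maximum would miss clipped crests that
  sit below an earlier, taller peak).  Any finding rejects the whole
  record.
- **Denoising**: 8-level db4 decomposition; A8 (< fs/512 ≈ 0.244 Hz,
  baseline) and D1–D2 (> fs/8 ≈ 15.6 Hz, artifacts) are zeroed, retaining
  the 0.244–15.6 Hz band that carries the PPG fundamental (~0.9–1.6 Hz
  here) and its harmonics.  The signal is odd-reflection padded (continuous
  value and slope) by min(n−1, 1024) samples before decomposition so the
  filter-bank boundary transient falls outside the returned samples; without
  this the edge error on a pure in-band-rejected tone is ~8%, with it
  < 1%.
- **Peak detection**: local maxima with minimum spacing fs·60/hr_max
  (hr_max 180 bpm) and prominence ≥ 0.3 × interquartile range.
- **Segmentation**: span i = (peak_i, peak_{i+2}), half-open, 0-based;
  n − 2 spans from n peaks, consecutive spans sharing one cycle.
- **Resampling**: natural cubic spline over the excerpt's index range,
  evaluated at 200 uniform query points including both endpoints.  Windows
  longer than 200 samples are compressed by the same spline — symmetric
  handling avoids a length-dependent bias between slow and fast heart
  rates.
- **Labels**: SBP = mean of per-beat ABP maxima in the span, DBP = mean of
  inter-peak trough minima (edge-partial troughs included).  ABP beats are
  found with prominence ≥ 0.5 × the window's peak-to-peak range — stricter
  than the PPG rule because the dicrotic bump on the pressure downstroke
  can otherwise be mistaken for a beat, which biases SBP low by tens of
  mmHg.  Averaging over the (usually two) beats in a span is robust to the
  window boundary cutting a beat.
- **Abnormal-pressure filter**: drop iff SBP ≥ 200, DBP ≥ 120, SBP ≤ 80,
  or DBP ≤ 40 — all four boundaries inclusive.
- **Standardization**: per segment, population σ (divide by N).  A
  zero-variance segment raises and is discarded upstream.

## Optimizers

Single-step functional implementations (`state, gradient → state`) of the
canonical forms:

- SGD: `W ← W − α·g`.
- RMSprop: `ms ← 0.9·ms + 0.1·g²; W ← W − α·g/(√ms + ε)`.
- Adam: decay rates 0.9/0.999, bias-corrected moments,
  `W ← W − α·m̂/(√û + ε)`.
- Adadelta: ρ = 0.9 accumulator recurrences,
  `ΔW = −α·(RMS[ΔW]/RMS[g])·g`.  Canonical Adadelta has no learning rate;
  α (default 1) is applied as a multiplier, as common framework
  implementations do, because the search grid varies the learning rate for
  every rule.

ε = 1e-8 throughout.  The training loop consumes these exact step
functions, so there is no separate "framework" path to keep equivalent.

## Models and training

All three architectures are built on a NumPy layer library
(`ppgbp.nn`) with hand-written reverse-mode gradients, verified against
central finite differences in the test suite.  Input convention: 200 time
steps × 1 feature; one scalar output; SBP and DBP use separately trained
models (the best hyperparameters generally differ per target).

- LSTM: 25 → 50 units, dropout 0.2, batch normalization, dense head.
- LSTM autoencoder: encoder 128/64/32/16 (bottleneck), repeat vector to
  200 steps, mirrored decoder 16/32/64/128, dropout 0.2, dense head on the
  final decoder state; Glorot-normal initialization; trained end-to-end on
  the pressure target (no reconstruction pre-training).
- CNN–LSTM: five blocks of (1-D conv, ReLU, max-pool 2) with filter counts
  (32, 64, 64, 128, 128) and kernel width 5 (the filter counts are a
  documented default, exposed in `ModelSpec`), dropout 0.1, one 64-unit
  LSTM over the pooled 6-step feature sequence, dense 64 → 1.  The
  temporal extent shrinks 200→100→50→25→12→6, so inputs must be ≥ 2⁵
  samples.

Training minimizes MSE in mini-batches, shuffled per epoch from the run
seed; dropout draws from the same generator, making runs bit-reproducible
under a fixed seed.  Targets are z-scored on the training labels and
predictions mapped back to mmHg — a fixed affine reparameterization that
keeps one learning-rate grid usable for both targets (SBP ≈ 135 ± 25 and
DBP ≈ 62 ± 10 otherwise need very different step sizes); recorded losses
are converted back to mmHg².  Early stopping watches validation MSE
(default patience 10, max 100 epochs) and restores the best weights.
Non-finite loss raises a training failure.

## Selection

Splitting uses floor rounding on both the train and test fractions with the
remainder discarded — for n = 75,226 at 80/20 this yields exactly 60,180
and 15,045 — and then carves validation from the train share (default 0.2,
giving 48,144/12,036/15,045; the reference cohort's published validation
count does not follow from any simple rule, so the fraction is exposed in
config).  Splits are segment-level by default to mirror the reference
setup; `subject_ids` enables the methodologically safer subject-level
split.  Grid search scores each of the 48 cells by mean validation MSE
over k folds (default 5), ties broken by lower SD then grid order; a
diverging cell scores +inf and the search continues.  The CV epoch budget
is deliberately small (configurable); the chosen cell is refit at full
budget.  Nesterov-momentum Adam variants are excluded: the grid is exactly
{sgd, rmsprop, adam, adadelta}.

## Evaluation

ME uses the reference − prediction sign convention; AAMI compares |ME| ≤ 5
and SD ≤ 8 (inclusive); IEEE bands are left-open/right-closed with A's
inclusive ≤ 5; BHS grades need all three CP thresholds of a band; below C
is D in both letter schemes.  Bland–Altman limits are d̄ ± 1.96·SD with the
same sample-SD (n − 1) as the AAMI dispersion term.  The report object
serializes to JSON and fixed-width text.

## Problem sizes in the test and acceptance runs

The suite's stochastic recovery check and `scripts/acceptance.py` use 21
synthetic records of 300 s (≈ 8,000 two-cycle segments) and train the
CNN–LSTM for 6 epochs with Adam (lr 0.001, batch 64) — sizes chosen so a
single-CPU run finishes in minutes while leaving a comfortable margin to
the acceptance bounds (test MAE < 8 mmHg SBP / < 5 mmHg DBP; observed ≈
1.3 / 0.8 at seed 1).  Unit tests use shorter records (10–120 s) and
reduced layer widths where only mechanics are under test.

## Known limitations

- The synthetic task is far easier than real ICU data; grades earned on it
  are statements about the pipeline, not about clinical accuracy.
- The NumPy training loop is single-threaded and unsuited to
  database-scale training.
- The LSTM autoencoder trains slowly over 200-step sequences (8 recurrent
  layers of BPTT); it is exercised at reduced width in tests.
- QC operates on the PPG trace only; a production system would also screen
  the ABP channel (damped lines, calibration steps).
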