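# ppgbp — cuffless blood-pressure estimation from PPG

`ppgbp` implements an end-to-end pipeline for estimating systolic and
diastolic blood pressure (SBP/DBP, mmHg) from the photoplethysmogram (PPG),
the optical pulse waveform measured by wearable and bedside sensors.  It is
aimed at researchers in physiological signal processing who want a fully
testable, dependency-light reference implementation of the classic
ICU-waveform recipe: beat-level PPG morphology in, per-beat arterial
pressures out, graded against the blood-pressure device-validation
standards.

The package covers:

- **Synthetic paired PPG/ABP records.**  Real pipelines train on ICU
  databases where a PPG and an invasive arterial-blood-pressure (ABP) line
  are recorded together at 125 Hz.  `ppgbp.synthetic` generates stand-in
  records with known per-beat (SBP, DBP) ground truth: each beat is a
  two-Gaussian pulse whose systolic width is a linear function of SBP and
  whose dicrotic-wave amplitude is a linear function of DBP, so a learnable,
  invertible BP → morphology mapping exists by construction.  An optional
  WFDB adapter (`load_wfdb_record`) reads real records when the `wfdb`
  package is installed.
- **Preprocessing** (`ppgbp.preprocessing`): flatline/flat-peak quality
  control; 8-level Daubechies-4 discrete wavelet decomposition with
  denoising by zeroing the baseline band A8 (< ~0.244 Hz) and the
  high-frequency details D1–D2 (> ~15.6 Hz); systolic-peak detection;
  segmentation into two-cycle peak-to-peak windows with one-cycle overlap;
  cubic-spline resampling of every window to 200 samples; reference label
  extraction from the ABP excerpt; removal of abnormal pressures
  (SBP ≥ 200, DBP ≥ 120, SBP ≤ 80, DBP ≤ 40); per-segment z-scoring,
  x ↦ (x − μ)/σ with the population σ.
- **Optimizers** (`ppgbp.optimizers`): from-scratch, single-step-testable
  SGD, RMSprop, Adam, and Adadelta update rules.
- **Models** (`ppgbp.models`): three sequence regressors from a 200-sample
  segment to one pressure value, built on a small NumPy layer library with
  hand-written backpropagation (`ppgbp.nn`) — a two-layer LSTM (25/50
  units), an LSTM autoencoder (4 + 4 layers with a repeat vector), and a
  CNN–LSTM (five conv/ReLU/max-pool blocks, one LSTM, two dense layers).
- **Selection** (`ppgbp.selection`): 80/20 train/test splitting with a
  validation carve-out, k-fold cross-validation, and exhaustive grid search
  over optimizer × learning rate {0.001, 0.01, 0.005, 0.05} × batch size
  {32, 64, 128} — 48 cells.
- **Evaluation** (`ppgbp.evaluation`): MAD, signed mean error (reference −
  prediction), sample SD of errors, cumulative percentages CP5/CP10/CP15,
  IEEE MAD bands (A ≤ 5 < B ≤ 6 < C ≤ 7 < D), BHS cumulative-percentage
  grades, the AAMI |ME| ≤ 5 & SD ≤ 8 criterion, and Bland–Altman limits of
  agreement d̄ ± 1.96·SD.

## Worked example

`examples/04_train_and_grade.py` preprocesses four 300-second synthetic
records (~1,600 segments), trains one CNN–LSTM per pressure target for five
epochs, and grades the held-out test predictions:

```
--- SBP ---
n segments        : 319
MAD               : 1.894 mmHg
ME                : -0.054 mmHg
SD of errors      : 2.338 mmHg
CP5 / CP10 / CP15 : 97.18% / 100.00% / 100.00%
IEEE grade        : A
BHS grade         : A
AAMI              : pass
Bland-Altman      : -0.054 mmHg [-4.636, 4.529]
```

MAD is the headline accuracy (mean |predicted − reference| in mmHg); ME and
SD feed the AAMI pass/fail rule; the CP values are the fractions of
predictions within 5/10/15 mmHg that determine the BHS letter grade; the
Bland–Altman line gives the mean difference and its 95% limits of
agreement.  On this synthetic task the mapping is recoverable almost
exactly, so all three standards come out at their top grade — the point of
the example is the mechanics, not the difficulty.

The other scripts in `examples/` walk through record synthesis, the
preprocessing chain, optimizer behavior on a quadratic, and grid search.
A thin CLI wraps the same stages:

```sh
ppgbp synth --n-records 4 --out records/
ppgbp preprocess records/*.tsv --out segments.tsv
ppgbp train segments.tsv --target sbp --out model_sbp
ppgbp evaluate segments.tsv model_sbp --target sbp
ppgbp run-all --out run/
```

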