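"""Run the preprocessing chain on one record and check label fidelity.

Chain: QC -> db4 wavelet denoising (drop A8 + D1-D2) -> systolic-peak
detection -> two-cycle segmentation with one-cycle overlap -> cubic-spline
resampling to 200 samples -> ABP label extraction -> abnormal-BP filter ->
per-segment z-scoring.
"""

import numpy as np

from ppgbp import (
    SyntheticConfig,
    dwt_denoise,
    detect_systolic_peaks,
    ground_truth_for_span,
    record_to_segments,
    subband_frequency_ranges,
    synth_record,
)

record = synth_record(SyntheticConfig(duration=120.0, seed=7))

for name, low, high in subband_frequency_ranges(record.sampling_rate, 8):
    kept = name not in ("A8", "D1", "D2")
    print(f"  band {name:3s}: {low:7.3f} - {high:7.3f} Hz   {'kept' if kept else 'zeroed'}")

denoised = dwt_denoise(record.ppg, record.sampling_rate)
peaks = detect_systolic_peaks(denoised, record.sampling_rate)
segments = record_to_segments(record)

errors = []
for seg in segments:
    true_sbp, true_dbp = ground_truth_for_span(record, *seg.span)
    errors.append((abs(seg.sbp - true_sbp), abs(seg.dbp - true_dbp)))
errors = np.array(errors)

print(f"systolic peaks found : {len(peaks)}")
print(f"segments produced    : {len(segments)} (= peaks - 2 minus filtered)")
print(f"segment length       : {len(segments[0].values)} samples, z-scored "
      f"(mean {segments[0].values.mean():+.1e}, sd {segments[0].values.std():.6f})")
print(f"label error vs truth : SBP {errors[:, 0].mean():.2f} mmHg, "
      f"DBP {errors[:, 1].mean():.2f} mmHg (mean abs)")
print("Labels come from ABP beat extrema inside each span; sub-2-mmHg error")
print("means the reference pressures the models learn from are trustworthy.")
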