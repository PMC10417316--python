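"""Generate a synthetic paired PPG/ABP record and inspect its ground truth.

The generator emulates an ICU-style acquisition: 300 s of paired signal at
125 Hz, heart rate and pressures drifting beat to beat, with the per-beat
systolic/diastolic pressures recorded before noise is added.
"""

import numpy as np

from ppgbp import SyntheticConfig, ground_truth_for_span, synth_record

record = synth_record(SyntheticConfig(duration=300.0, sampling_rate=125.0, seed=42))

sbps = np.array([b[1] for b in record.beats])
dbps = np.array([b[2] for b in record.beats])
print(f"record length      : {len(record)} samples "
      f"({len(record) / record.sampling_rate:.0f} s at {record.sampling_rate:.0f} Hz)")
print(f"beats              : {len(record.beats)}")
print(f"SBP range          : {sbps.min():.1f} - {sbps.max():.1f} mmHg")
print(f"DBP range          : {dbps.min():.1f} - {dbps.max():.1f} mmHg")
sbp, dbp = ground_truth_for_span(record, 0, 2000)
print(f"truth in [0, 2000) : SBP {sbp:.1f} / DBP {dbp:.1f} mmHg")
print("The beats list is the reference every downstream stage is tested against.")
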