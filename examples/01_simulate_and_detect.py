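"""Simulate a 5-minute ECG and recover every beat with the detector.

The generator places each R apex analytically, so detection accuracy can
be measured exactly against ground truth.
"""

import numpy as np

from hrvstress import detect, match_annotations
from hrvstress.synth import SynthConfig, simulate_record

record, truth = simulate_record(SynthConfig(seed=7))
result = detect(record)
stats = match_annotations(result, truth)

print(f"simulated beats : {len(truth)}")
print(f"detected beats  : {len(result)}")
print(f"missed / false  : {stats.missed} / {stats.false_pos}")
print(f"recognition rate: {stats.recognition_rate:.2f} %")
err = np.max(np.abs(result.r_indices - truth.indices))
print(f"worst apex error: {err} sample(s) at {record.fs:g} Hz")

# A 100% rate with sub-sample-scale errors means the windowed candidate
# search and RR-based reconciliation located every apex exactly.
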