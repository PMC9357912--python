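"""Gate an RR series and compute the eight HRV parameters.

An ectopic-like jump is injected to show the 0.12 s gating rule discarding
it before the parameters are computed on a clean 256-interval segment.
"""

import numpy as np

from hrvstress import compute_parameters, detect, gate_rr
from hrvstress.synth import SynthConfig, simulate_record

record, _ = simulate_record(SynthConfig(seed=3))
rr = detect(record).rr_intervals.copy()
rr[50] += 0.4  # a premature-beat-like outlier

segments = gate_rr(rr)
seg = segments[0]
print(f"intervals in: {rr.size}, discarded by gating: {seg.removed_count}, "
      f"segments of 256: {len(segments)}")

params = compute_parameters(seg)
for name, value in params.to_dict().items():
    print(f"  {name:6s} = {value:.3f}")

# SDNN/pNN50/HR summarise overall and beat-to-beat variability; TP and
# LF/HF the spectral balance; VAI/HRD/HLE the Poincare geometry, relative
# dispersion and divergence rate of the interval series.
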