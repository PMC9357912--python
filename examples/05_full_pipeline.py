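"""The full chain: synthetic ECG -> beats -> HRV segment -> stress index."""

from hrvstress import (compute_parameters, detect, gate_rr, match_annotations,
                       stress_index)
from hrvstress.synth import SynthConfig, simulate_record

record, truth = simulate_record(SynthConfig(seed=7))
beats = detect(record)
print(f"recognition rate: "
      f"{match_annotations(beats, truth).recognition_rate:.1f} %")

segment = gate_rr(beats.rr_intervals)[0]
params = compute_parameters(segment)
result = stress_index(params)
print(f"criterion scores: z1={result.z1:.3f} z2={result.z2:.3f} z3={result.z3:.3f}")
print(f"stress index Z  : {result.z:.1f} / 100")

# z1..z3 are the frequency-domain, time-domain and non-linear criterion
# scores (fractions); Z weighs them by the criterion-layer AHP weights.
# A resting simulation lands near the relaxed end of the scale.
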