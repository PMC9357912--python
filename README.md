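# hrvstress

Quantitative mental-stress assessment from single-lead ECG: an improved
differential-threshold R-wave detector, RR-interval gating, a
heart-rate-variability (HRV) parameter suite, and an analytic-hierarchy-process
(AHP) weighted stress index — plus a synthetic ECG generator with exact
ground-truth beat positions so the whole pipeline is verifiable without any
external recordings.

## Who this is for

Engineers and researchers building wearable or low-compute ECG analysis:
the detector needs only an argmax, a first difference and simple
bookkeeping per beat, yet tracks heart-rate changes through a dynamic
search window; the stress model turns eight standard HRV parameters into a
single interpretable 0–100 index.

## The pipeline

1. **R-wave detection.** From detection point `L`, a window of width
   `1.5 × RR̄` (clamped to [0.4, 2.0] s) is searched for two candidates: the
   window amplitude maximum `R₁`, and `R′`, the amplitude maximum between
   the extrema of the first-difference signal. Agreeing candidates are the
   beat; disagreeing ones are resolved toward the candidate whose implied
   RR interval is closer to the running RR (the earlier peak before any
   history exists). The next search starts at `R + T₁` with `T₁ = 0.2` s.
   A start-point rule (`A_max > 1.8 · B_max` over two 0.8 s probe segments)
   avoids launching the search on top of an R wave.
2. **Gating.** Successive RR differences must stay below 0.12 s; offending
   intervals are discarded, the remainder spliced, and runs of 256
   consecutive intervals become HRV segments.
3. **HRV parameters.** Per segment: SDNN, pNN50, mean HR; total power and
   LF/HF from a Welch spectrum of the 4 Hz-resampled tachogram
   (LF 0.04–0.15 Hz, HF 0.15–0.40 Hz); Poincaré vector angle index (VAI),
   relative dispersion (HRD), and the largest Lyapunov exponent (HLE,
   Rosenstein method).
4. **Stress index.** AHP judgment matrices (Saaty 1–9 scale, consistency
   ratio < 0.1 enforced) yield priority weights β and λ; normalised
   parameter terms are combined into criterion scores
   `Z_G1 = λ₁₁·LF/HF⁄15 + λ₁₂·TP⁄9000`, `Z_G2`, `Z_G3` and the target index
   `Z = Σ 100·βᵢ·Z_Gi ∈ [0, 100]`.

## Worked example

```sh
hrvstress run --preset clean5min --seed 7 --out report.json
```

simulates a clean 5-minute ECG (360 Hz, 70 bpm with physiological RR
variability), detects beats, scores them against the generator's ground
truth, gates the RR series and computes HRV and stress. The report contains:

```
"recognition": {"n_ref": 354, "missed": 0, "false_pos": 0, "recognition_rate": 100.0}
"hrv":    {"lf_hf": 2.525, "tp": 180.795, "sdnn": 26.398, "pnn50": 0.0,
           "hr": 72.205, "hle": 2.384, "hrd": 0.032, "vai": 0.248}
"stress": {"z1": 0.131, "z2": 0.904, "z3": 0.502, "z": 34.276, "clamped": []}
```

All 354 simulated beats were recognised with no misses or false positives.
The gated segment shows a mildly LF-dominant spectrum (LF/HF ≈ 2.5), normal
short-term variability (SDNN ≈ 26 ms at HR ≈ 72 bpm), and the combined
index Z ≈ 34 — the relaxed end of the scale, consistent with a resting
simulation.

The same stages are available from Python:

```python
from hrvstress import detect, gate_rr, compute_parameters, stress_index
from hrvstress.synth import SynthConfig, simulate_record

record, truth = simulate_record(SynthConfig(seed=7))
beats = detect(record)
segment = gate_rr(beats.rr_intervals)[0]
result = stress_index(compute_parameters(segment))
print(round(result.z, 1))   # 34.3
```

Short narrative scripts, one per capability, live in `examples/`. Other
subcommands: `simulate`, `detect`, `evaluate` (score detections against
reference annotations), `hrv`, `stress`, and `stress-table` (score a
before/after table of HRV parameter rows and report per-subject percent
changes). WFDB records (formats 16/212, MIT-BIH style, including beat
annotations), two-column CSV and plain-text annotation files are supported.

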