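# Methods

## Scope and model

`hrvstress` quantifies mental stress from single-lead ECG in four stages:
R-wave detection, RR-interval gating, HRV parameter computation, and an
analytic-hierarchy-process (AHP) weighted stress index. A synthetic ECG
generator with exact ground-truth beat positions makes every stage testable
without external recordings.

## R-wave detection (differential-threshold algorithm)

The detector exploits the R wave's two signatures: it is the tallest
deflection of a beat and carries the steepest rising/falling slopes, so the
first difference of the signal peaks immediately before and dips immediately
after the apex.

**Start-point rule.** With probe length `t_init` (default 0.8 s, roughly one
nominal beat period), the maxima `A_max = max(x[0:t])` and
`B_max = max(x[t:2t])` (with `t = round(t_init · fs)`) are compared. If
`A_max > 1.8 · B_max` the record opens on top of an R wave — a search window
straddling an apex reverses the order of the slope extrema and causes
misses — so detection starts at sample `2t`; otherwise at sample 0. When the
rule fires, beats inside the first `2t` samples are deliberately not
searched; this is the algorithm's defined behaviour, and on a 5-minute record
it can cost at most the opening one or two beats.

**Windowed candidate search.** From detection point `L` a window of the
current width is sliced. Two candidates are formed: `R1`, the window argmax,
and `R'`, the argmax of the window restricted to the inclusive span between
the argmax and argmin of the first difference. The span is taken regardless
of the extrema's order so inverted or atypical beats still produce a bracket.
Ties in every argmax/argmin resolve to the lowest index.

**Reconciliation.** If `R1 == R'` that index is the beat. Candidates within
30 ms of one another are treated as the same QRS complex and resolve to the
amplitude maximum `R1` (the slope bracket can sit a few samples off-apex when
the next beat's rising edge is clipped by the window end). Genuinely distinct
candidates are resolved by RR history: the candidate whose implied interval
is closer to the reference RR wins; before any history exists the earlier
candidate wins, since the straddling case puts the true apex early in the
window.

**RR tracking and the dynamic window.** After each accepted beat the search
restarts at `R + T1` with `T1 = 0.2 s` (the ventricular refractory period).
Once intervals exist, the window width is `1.5 ×` a running RR estimate,
clamped to [0.4, 2.0] s. The running estimate is the **median of the last 8
accepted intervals**, and the reconciliation reference is the median of the
last 5: a single missed or doubled interval otherwise drags a mean-based
estimate enough to make the reconciliation prefer doubled intervals on every
subsequent window (alternate-beat misses at high heart rates). Windows that
would run past the record end are clipped, not dropped, so tail beats remain
detectable; a window shorter than 3 samples ends the search.

**Beat acceptance.** A window yields a beat only if its prominence
(argmax value minus window median — invariant to amplitude scaling and DC
offset) is positive and at least `accept_frac = 0.35` of a running beat
prominence. The running prominence is seeded from the two start-point probe
segments, which contain at least one beat whenever the heart rate exceeds
~38 bpm; without this seed, a beat-free opening window at slow heart rates
is accepted on numerically-zero prominence and the tracker never recovers.
Rejected windows advance the search by their full width. An all-zero or
beat-free record therefore returns an empty result with a warning status.

**Two-beat windows.** Before the dynamic width has locked in (or at heart
rates above ~150 bpm) a window can span two beats, and both candidates can
land on the *later* one. A guard runs after reconciliation: if a local
maximum reaching half the window prominence precedes the chosen index by
more than a refractory period, that earlier peak is the beat — the later one
is found by the next window. The same peak search snaps a choice that is
within the 30 ms same-QRS tolerance of a prominent local maximum onto that
maximum.

**Optional pre-filter.** A zero-phase 5–20 Hz Butterworth band-pass is
available behind `DetectorConfig(bandpass=True)`; default off — the
algorithm is designed to run on the raw signal.

**Evaluation.** Detections and reference beats are matched one-to-one,
greedily by increasing time difference within a ±50 ms tolerance; the
construction is symmetric, so swapping the roles of the two sets swaps
missed and false-positive counts. The recognition rate is
`100 · (N − missed − false) / N` over `N` reference beats.

## RR gating

HRV analysis presumes sinus rhythm. Scanning left to right, an interval is
kept iff it is the first kept interval or differs from the previously kept
one by less than 0.12 s; rejected intervals are discarded and the stream is
spliced across the gap. The kept stream is cut into consecutive runs of
exactly 256 intervals; a shorter trailing run is not analysed (a non-strict
mode in the CLI analyses arbitrary-length sequences for toy inputs). The
output provably satisfies its own acceptance predicate, and with the
threshold at infinity the rule degenerates to partitioning by length alone.

## HRV parameters

* **SDNN** — sample (n−1) standard deviation of RR, in ms.
* **pNN50** — percentage of successive RR differences strictly greater than
  50 ms.
* **HR** — 60 / mean(RR), bpm.
* **TP, LF, HF, LF/HF** — the tachogram (RR in ms vs cumulative beat time)
  is cubic-spline interpolated onto a uniform 4 Hz grid, mean-removed, and a
  Welch spectrum (Hann window, 128-sample segments, 50 % overlap) is
  integrated over 0.0033–0.40 Hz (TP), 0.04–0.15 Hz (LF) and 0.15–0.40 Hz
  (HF), all in ms². LF/HF is NaN when HF is zero (a constant tachogram), and
  band powers of a constant tachogram are exactly zero. LF + HF cannot
  exceed TP beyond integration tolerance because the bands are disjoint
  sub-ranges of the TP band.
* **VAI** (vector angle index) — mean over Poincaré points
  `(RR_i, RR_{i+1})` of `|θ_i − 45°|` with `θ_i = atan2(RR_{i+1}, RR_i)`, in
  degrees; zero for a constant series.
* **HRD** (relative dispersion) — coefficient of variation
  `std(RR)/mean(RR)`.
* **HLE** — largest Lyapunov exponent of the RR series by the Rosenstein
  small-data method: delay embedding (dimension 5, delay 1), nearest
  neighbours outside a temporal exclusion window, least-squares slope of the
  mean log-divergence curve over its first five steps, in units of 1/beat.
  A non-diverging (e.g. constant) series returns 0. `nonlinear()` reports
  HLE on a ×10 amplified log-divergence scale (`lyap_scale=10`), which
  places typical 5-minute segments in the single-digit range that the
  stress model's normalisation bound (10) expects; the raw per-beat
  estimator is exposed as `largest_lyapunov_exponent` and recovers ln 2 for
  the logistic map at r = 4 to within a few percent. The reporting scale is
  a declared convention — the literature defines no canonical unit for this
  quantity in HRV work — and is configurable.

## AHP stress model

Criteria (frequency-domain, time-domain, non-linear) and the parameters
within each criterion are compared pairwise on Saaty's 1–9 scale. The four
shipped judgment matrices are the model's single source of truth: weights
are always computed from them at run time, never hard-coded. Priority
weights are principal right eigenvectors obtained by power iteration
(tolerance 1e-12); the row-geometric-mean method is exposed as a cross-check
and agrees with the eigenvector weights to three decimals on all four
matrices. Saaty's consistency ratio `CR = ((λ_max − n)/(n − 1)) / RI` must
be below 0.1; the shipped matrices give CR ≈ 0.074 (criterion layer), 0
(frequency pair and the exactly consistent time-domain matrix) and ≈ 0.016
(non-linear).

Each parameter maps onto a [0, 1] stress-direction term through fixed
normalisation bounds (LF/HF ∕ 15, TP ∕ 9000 ms², (200 − SDNN) ∕ 200 ms,
(60 − PNN50) ∕ 60 %, HR ∕ 100 bpm, HLE ∕ 10, (0.4 − HRD) ∕ 0.4,
(10 − VAI) ∕ 10). Every term is clamped to [0, 1] before weighting — the
model is otherwise undefined for out-of-range inputs such as SDNN above
200 ms — and clamp events are recorded in the result. Criterion scores are
kept as fractions and the target index is `Z = Σ 100 · β_i · Z_Gi`, giving a
0–100 scale; treating the criterion scores as percentages here would
double-scale the index and is inconsistent with relaxed-state values near
30. Within the bounds, Z rises strictly with LF/HF, TP, HR and HLE and
falls strictly with SDNN, PNN50, HRD and VAI.

The two shipped five-subject before/after tables (exercise; calm-then-scary
video) serve as worked examples: every subject's index rises after the
stressor, the largest video-experiment increase computes to ≈ 106.8 %, and
the relaxed-state rows average ≈ 31.4.

## Synthetic ECG generator

Each beat is a sum of five Gaussian deflections (P, Q, R, S, T) with fixed
offsets, amplitudes and widths (R: 1.5 mV, σ = 12 ms at offset 0); the
tall narrow R wave dominates both amplitude and slope content, which is the
structure the detector exploits. The defaults are fs = 360 Hz (the MIT-BIH
convention), 300 s duration, 70 bpm mean heart rate and 0.03 s RR
variability. Beat k's apex sits at the k-th cumulative RR time, so the
first beat appears one full interval after the record starts; annotations
are the nearest sample to each apex, hence detector accuracy is measurable
to ±1 sample.

The RR process is `60/HR + Σ a_j sin(2π f_j t) + w_i`: optional sinusoidal
modulation (respiratory/vasomotor emulation) plus a bounded AR(1) Gaussian
walk with lag-1 correlation 0.95, stationary standard deviation `rr_sd`,
bound ±10 % of the mean interval, and a 0.3 s physiological floor.
Noise components — baseline wander (0.3 Hz sinusoid), powerline hum (50 Hz
sinusoid) and broadband white noise — are scaled to a requested SNR in dB
relative to the mean-removed power of the clean signal; `mixed_noise(10)`
splits a 10 dB budget equally across the three. All generators are
bit-reproducible per seed.

What the generator does **not** emulate: real QRS morphology variation,
ectopic beats and arrhythmias, electrode-motion artefacts, muscle noise, or
respiration-coupled amplitude modulation. Perfect recognition on these
synthetics therefore demonstrates the algorithm's windowing/reconciliation
logic and noise tolerance, not clinical-grade performance on pathological
recordings; the `evaluate` command exists precisely so users with annotated
clinical records (e.g. the MIT-BIH arrhythmia database, whose formats
`ecg_io` reads) can score the detector on real data.

A parameter-vector sampler draws the eight HRV quantities uniformly within
the per-state (relaxed/stressed) empirical ranges of the shipped tables,
exercising the stress model across realistic operating points: sampled
relaxed vectors score below sampled stressed vectors in ≥ 95 of 100 paired
draws.

## Problem sizes and numerical choices

Tests and the acceptance script use 300 s records for headline detection
checks (≈ 350–500 beats each; one clean record, twenty noisy ones) and 60 s
records for the 100-seed sweep across 40–180 bpm — sizes chosen so each
property is exercised over hundreds of beats per condition while the whole
suite stays interactive. Power iteration tolerance is 1e-12; reciprocal
matrices are validated to 1e-9; CSV sampling must be uniform to 1 % of the
median step; WFDB support covers formats 16 and 212 (single- and
dual-channel), with everything else rejected explicitly.

## Known limitations

* The detector assumes upright-dominant R waves; fully inverted QRS
  complexes survive the slope bracket but the prominence guard assumes the
  apex is a maximum.
* At heart rates above ~180 bpm the refractory delay plus the minimum
  window width no longer guarantees single-beat windows.
* The HLE reporting scale is a convention (see above); compare HLE values
  only within this package's convention.
* Gating splices across removed intervals, so a segment can bridge a
  (bounded) discontinuity in time; spectral estimates treat the spliced
  sequence as contiguous, as the gating procedure defines.
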