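"""AHP-weighted mental-stress index from HRV parameters.

The model arranges the eight HRV parameters in a three-level hierarchy --
target (body stress Z), criteria (frequency-domain G1, time-domain G2,
non-linear G3) and scheme layer (the parameters themselves) -- and scores
it with analytic-hierarchy-process weights.  Pairwise 1-9 judgment
matrices encode how strongly each criterion (and each parameter within a
criterion) drives mental stress; priority weights are the principal right
eigenvectors of those matrices, and each matrix must pass Saaty's
consistency check CR < 0.1 before its weights are trusted.

Each parameter is mapped to a [0, 1] "stress direction" term through a
fixed normalisation bound -- rising LF/HF, TP, HR and HLE score towards 1,
while falling SDNN, pNN50 and the complements of HRD and VAI do -- and the
criterion scores are the weighted sums

    Z_G1 = l11*(LFHF/15)        + l12*(TP/9000)
    Z_G2 = l21*(200-SDNN)/200   + l22*(60-PNN50)/60 + l23*(HR/100)
    Z_G3 = l31*(HLE/10)         + l32*(0.4-HRD)/0.4 + l33*(10-VAI)/10

with every term clamped to [0, 1] before weighting.  The target index is
Z = sum_i 100 * beta_i * Z_Gi, a 0-100 scale.

The module also ships the two before/after experiment tables (exercise and
video stimulus) whose rows serve as worked examples, and whose per-state
ranges calibrate the synthetic parameter sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .hrv import HRVParameterVector

__all__ = [
    "JudgmentMatrix",
    "WeightSet",
    "NormalizationBounds",
    "StressResult",
    "MATRIX_A",
    "MATRIX_B1",
    "MATRIX_B2",
    "MATRIX_B3",
    "priority_vector",
    "geometric_mean_vector",
    "consistency_ratio",
    "default_weights",
    "criterion_scores",
    "stress_index",
    "stress_change",
    "TableRow",
    "EXERCISE_TABLE",
    "VIDEO_TABLE",
    "score_table",
]

# Saaty's random consistency index by matrix order.
_RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                 7: 1.32, 8: 1.41, 9: 1.45}


@dataclass(frozen=True)
class JudgmentMatrix:
    """A square positive reciprocal pairwise-comparison matrix (1-9 scale)."""

    entries: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("judgment matrix must be square")
        if np.any(m <= 0):
            raise InputError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise InputError("judgment matrix diagonal must be 1")
        if not np.allclose(m * m.T, 1.0, atol=1e-9):
            raise InputError("judgment matrix must be reciprocal: a_ji = 1/a_ij")
        object.__setattr__(self, "entries", m)
        if not self.labels:
            object.__setattr__(self, "labels",
                               tuple(f"x{i + 1}" for i in range(m.shape[0])))

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])


# Criterion-layer matrix: frequency domain vs time domain vs non-linear.
MATRIX_A = JudgmentMatrix(np.array([
    [1.0, 4.0, 5.0],
    [1 / 4, 1.0, 3.0],
    [1 / 5, 1 / 3, 1.0]]), labels=("frequency", "time", "nonlinear"))

# Scheme-layer matrices.
MATRIX_B1 = JudgmentMatrix(np.array([
    [1.0, 3.0],
    [1 / 3, 1.0]]), labels=("lf_hf", "tp"))

MATRIX_B2 = JudgmentMatrix(np.array([
    [1.0, 1.0, 3.0],
    [1.0, 1.0, 3.0],
    [1 / 3, 1 / 3, 1.0]]), labels=("sdnn", "pnn50", "hr"))

MATRIX_B3 = JudgmentMatrix(np.array([
    [1.0, 3.0, 4.0],
    [1 / 3, 1.0, 2.0],
    [1 / 4, 1 / 2, 1.0]]), labels=("hle", "hrd", "vai"))


def priority_vector(m: JudgmentMatrix, tol: float = 1e-12,
                    max_iter: int = 10_000) -> np.ndarray:
    """Principal right eigenvector by power iteration, normalised to sum 1."""
    a = m.entries
    w = np.full(m.n, 1.0 / m.n)
    for _ in range(max_iter):
        v = a @ w
        v /= v.sum()
        if np.max(np.abs(v - w)) < tol:
            w = v
            break
        w = v
    return w


def geometric_mean_vector(m: JudgmentMatrix) -> np.ndarray:
    """Row-geometric-mean weights; a cross-check on the eigenvector method."""
    g = np.prod(m.entries, axis=1) ** (1.0 / m.n)
    return g / g.sum()


def consistency_ratio(m: JudgmentMatrix) -> tuple[float, float, float]:
    """(lambda_max, CI, CR) per Saaty; CR is 0 by definition for n <= 2."""
    if m.n > 9:
        raise InputError("consistency ratio defined here for n <= 9 only")
    w = priority_vector(m)
    lambda_max = float(np.mean((m.entries @ w) / w))
    if m.n <= 2:
        return lambda_max, 0.0, 0.0
    ci = (lambda_max - m.n) / (m.n - 1)
    cr = ci / _RANDOM_INDEX[m.n]
    return lambda_max, ci, cr


@dataclass(frozen=True)
class WeightSet:
    """Criterion weights beta and scheme weights lambda_1..lambda_3."""

    beta: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beta", "lambda1", "lambda2", "lambda3"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-9:
                raise InputError(f"{name} must be positive and sum to 1")
            object.__setattr__(self, name, v)

    @property
    def k(self) -> int:
        return int(self.beta.size)


def default_weights(method: str = "eigenvector") -> WeightSet:
    """Weights computed from the four shipped judgment matrices.

    The matrices remain the single source of truth: nothing here is
    hard-coded.  ``method`` selects ``eigenvector`` (canonical AHP) or
    ``geometric_mean``.
    """
    fn = {"eigenvector": priority_vector, "geometric_mean": geometric_mean_vector}
    if method not in fn:
        raise InputError(f"unknown weight method {method!r}")
    f = fn[method]
    return WeightSet(beta=f(MATRIX_A), lambda1=f(MATRIX_B1),
                     lambda2=f(MATRIX_B2), lambda3=f(MATRIX_B3))


@dataclass(frozen=True)
class NormalizationBounds:
    """Fixed denominators mapping each parameter onto [0, 1]."""

    lf_hf_max: float = 15.0
    tp_max: float = 9000.0    # ms^2
    sdnn_max: float = 200.0   # ms
    pnn50_max: float = 60.0   # %
    hr_max: float = 100.0     # bpm
    hle_max: float = 10.0
    hrd_max: float = 0.4
    vai_max: float = 10.0

    def __post_init__(self) -> None:
        if any(getattr(self, f) <= 0 for f in
               ("lf_hf_max", "tp_max", "sdnn_max", "pnn50_max",
                "hr_max", "hle_max", "hrd_max", "vai_max")):
            raise InputError("all normalisation bounds must be positive")


@dataclass(frozen=True)
class StressResult:
    """Criterion scores (fractions), the 0-100 index, and provenance."""

    z1: float
    z2: float
    z3: float
    z: float
    weights: WeightSet
    clamped: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"z1": self.z1, "z2": self.z2, "z3": self.z3, "z": self.z,
                "clamped": list(self.clamped)}


def _clamp(value: float, name: str, log: list[str]) -> float:
    if value < 0.0 or value > 1.0:
        log.append(name)
    return min(max(value, 0.0), 1.0)


def criterion_scores(p: HRVParameterVector, w: WeightSet,
                     b: NormalizationBounds = NormalizationBounds()
                     ) -> tuple[float, float, float, tuple[str, ...]]:
    """Z_G1..Z_G3 as fractions in [0, 1], with per-term clamping.

    A NaN LF/HF (undefined ratio) contributes as a clamped-to-zero term.
    """
    log: list[str] = []
    lf_hf = 0.0 if np.isnan(p.lf_hf) else p.lf_hf
    if np.isnan(p.lf_hf):
        log.append("lf_hf(nan)")
    z1 = (w.lambda1[0] * _clamp(lf_hf / b.lf_hf_max, "lf_hf", log)
          + w.lambda1[1] * _clamp(p.tp / b.tp_max, "tp", log))
    z2 = (w.lambda2[0] * _clamp((b.sdnn_max - p.sdnn) / b.sdnn_max, "sdnn", log)
          + w.lambda2[1] * _clamp((b.pnn50_max - p.pnn50) / b.pnn50_max, "pnn50", log)
          + w.lambda2[2] * _clamp(p.hr / b.hr_max, "hr", log))
    z3 = (w.lambda3[0] * _clamp(p.hle / b.hle_max, "hle", log)
          + w.lambda3[1] * _clamp((b.hrd_max - p.hrd) / b.hrd_max, "hrd", log)
          + w.lambda3[2] * _clamp((b.vai_max - p.vai) / b.vai_max, "vai", log))
    return z1, z2, z3, tuple(log)


def stress_index(p: HRVParameterVector, w: WeightSet | None = None,
                 b: NormalizationBounds = NormalizationBounds()) -> StressResult:
    """The target-layer index Z = sum_i 100 * beta_i * Z_Gi on a 0-100 scale."""
    if w is None:
        w = default_weights()
    z1, z2, z3, clamped = criterion_scores(p, w, b)
    z = float(100.0 * (w.beta[0] * z1 + w.beta[1] * z2 + w.beta[2] * z3))
    return StressResult(z1=z1, z2=z2, z3=z3, z=z, weights=w, clamped=clamped)


def stress_change(before: StressResult, after: StressResult) -> float:
    """Percent change of the index; NaN when the baseline index is 0."""
    if before.z == 0:
        return float("nan")
    return 100.0 * (after.z - before.z) / before.z


# ---------------------------------------------------------------------------
# Worked-example tables: five subjects each, measured before/after a
# stressor (exercise; watching a frightening video after a calm one).
# Columns: VAI, HRD, HLE, HR, SDNN, PNN50, TP, LF/HF.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableRow:
    subject: int
    state: str  # "before" | "after"
    params: HRVParameterVector


def _row(subject, state, vai, hrd, hle, hr, sdnn, pnn50, tp, lf_hf):
    return TableRow(subject, state, HRVParameterVector(
        lf_hf=lf_hf, tp=tp, sdnn=sdnn, pnn50=pnn50, hr=hr,
        hle=hle, hrd=hrd, vai=vai))


EXERCISE_TABLE: tuple[TableRow, ...] = (
    _row(1, "before", 1.11, 0.07, 5.01, 81, 54.20, 4.70, 1365, 0.29),
    _row(1, "after", 0.73, 0.07, 7.48, 99, 35.26, 1.90, 1929, 10.45),
    _row(2, "before", 1.06, 0.06, 5.64, 80, 42.63, 5.10, 1914, 0.30),
    _row(2, "after", 0.88, 0.05, 6.71, 102, 21.43, 1.10, 3924, 3.86),
    _row(3, "before", 1.39, 0.06, 5.80, 73, 34.01, 9.80, 1700, 0.51),
    _row(3, "after", 0.89, 0.06, 6.35, 95, 24.36, 1.90, 2042, 7.28),
    _row(4, "before", 1.08, 0.08, 5.22, 79, 68.98, 5.90, 4920, 0.21),
    _row(4, "after", 0.03, 0.05, 5.26, 100, 63.36, 1.20, 6743, 2.23),
    _row(5, "before", 1.27, 0.07, 5.76, 80, 46.17, 7.90, 1675, 1.26),
    _row(5, "after", 0.91, 0.07, 6.21, 98, 30.12, 2.80, 2485, 2.05),
)

VIDEO_TABLE: tuple[TableRow, ...] = (
    _row(1, "before", 1.12, 0.05, 5.86, 77, 52.85, 4.11, 1728, 0.76),
    _row(1, "after", 0.65, 0.05, 7.07, 90, 37.44, 0.98, 3415, 5.25),
    _row(2, "before", 2.52, 0.06, 5.12, 70, 32.29, 0.78, 2992, 0.35),
    _row(2, "after", 1.11, 0.06, 7.48, 97, 21.58, 0.0, 4469, 3.88),
    _row(3, "before", 1.06, 0.05, 4.96, 72, 48.04, 2.54, 2210, 0.26),
    _row(3, "after", 0.84, 0.03, 6.71, 98, 34.41, 0.0, 5264, 3.94),
    _row(4, "before", 2.61, 0.11, 5.63, 80, 51.70, 9.59, 2426, 0.90),
    _row(4, "after", 1.05, 0.06, 6.68, 87, 44.42, 0.78, 3262, 6.50),
    _row(5, "before", 1.26, 0.07, 5.35, 77, 52.85, 2.15, 822, 1.01),
    _row(5, "after", 0.65, 0.05, 7.27, 90, 25.29, 0.39, 3415, 8.18),
)


def score_table(rows, w: WeightSet | None = None,
                b: NormalizationBounds = NormalizationBounds()):
    """Score a before/after table.

    Returns a dict with per-row results, per-subject percent changes, the
    maximum change, and the mean of the "before" indices.
    """
    if w is None:
        w = default_weights()
    results = [(r.subject, r.state, stress_index(r.params, w, b)) for r in rows]
    by_subject: dict[int, dict[str, StressResult]] = {}
    for subject, state, res in results:
        by_subject.setdefault(subject, {})[state] = res
    changes = {s: stress_change(d["before"], d["after"])
               for s, d in by_subject.items() if "before" in d and "after" in d}
    before_vals = [res.z for _, state, res in results if state == "before"]
    return {
        "rows": results,
        "changes": changes,
        "max_change": max(changes.values()) if changes else float("nan"),
        "mean_before": float(np.mean(before_vals)) if before_vals else float("nan"),
    }
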