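"""Random position weight matrices (RPWMs).

A candidate repeat profile is not learned from an alignment: it is *drawn
at random* and later optimised by the genetic algorithm.  Generation has
three stages:

1. a frequency matrix is accumulated by laying a random equiprobable
   sequence of length L1 alongside the periodic position track
   1,2,…,n,1,2,…;
2. each count is turned into a binomial z-score,
   m1 = (m − L1·p) / sqrt(L1·p·(1−p)) with p = x(i)·y(j)/L1²;
3. the matrix is standardised so that every matrix in the population has
   the same squared norm R² (default 110·n, i.e. a constant per-cell
   second moment of 27.5) and the same background projection
   K_d = Σ m1(i,j)·p1(i)·p2(j) = −1.5, where p1 is the mononucleotide
   composition of the scanned window and p2(j) = 1/n.

Sharing R² and K_d makes alignment scores comparable across matrices —
the precondition for using the best score as a GA fitness.

Standardisation is the affine map M' = a·M + b·B with background matrix
B(i,j) = p1(i)·p2(j): K_d is linear and R² quadratic in (a, b), so the
constraints reduce to a quadratic in ``a`` with a unique positive root
whenever the R² target exceeds the norm attainable by B alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: R² target is R2_COEFF / n**R2_EXPONENT; K_d target is KD_TARGET.
#: The default law R² = 110·n keeps the per-cell second moment constant
#: (110/4 = 27.5, cell rms ≈ 5.2) for every period, so the score scale of
#: a 650-nt window is comparable across n = 2..50: shuffled sequence
#: scores ≈ 30–90 under any period while a clean repeat array scores
#: several hundred, which is what makes a single detection threshold
#: (F0 = 390) meaningful.  The mutation range ±10 of the genetic
#: algorithm is ≈ ±2 cell rms on this scale.  All three constants are
#: configuration values and can be overridden per call.
R2_COEFF = 110.0
R2_EXPONENT = -1.0
KD_TARGET = -1.5

#: length of the random generating sequence S1
DEFAULT_L1 = 10_000

N_MIN, N_MAX = 2, 50

UNIFORM_BACKGROUND = np.full(4, 0.25)


def r2_target(n: int, coeff: float | None = None, exponent: float | None = None) -> float:
    if coeff is None:
        coeff = R2_COEFF
    if exponent is None:
        exponent = R2_EXPONENT
    return coeff / float(n) ** exponent


@dataclass
class FrequencyMatrix:
    """4×n counts of a random sequence against the periodic track."""

    counts: np.ndarray  # (4, n) int64
    n: int
    L1: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, self.n):
            raise ValueError("counts must be 4×n")
        if self.counts.min() < 0:
            raise ValueError("negative count")
        if self.counts.sum() != self.L1:
            raise ValueError("counts must sum to L1")


@dataclass
class WeightMatrix:
    """A 4×n real scoring matrix; the GA's organism."""

    weights: np.ndarray  # (4, n) float64
    n: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (4, self.n):
            raise ValueError("weights must be 4×n")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weight")

    @property
    def r2(self) -> float:
        return float(np.sum(self.weights**2))

    def kd(self, background: np.ndarray) -> float:
        p1 = np.asarray(background, dtype=float)
        return float(self.weights.sum(axis=1) @ p1 / self.n)

    def consensus(self) -> str:
        """Highest-scoring base per column (paper-style consensus)."""
        from .seqio import BASE_OF

        return "".join(BASE_OF[int(i) + 1] for i in self.weights.argmax(axis=0))


@dataclass
class MatrixSet:
    """A population of weight matrices of common period with fitness vector.

    ``weights`` is an (N, 4, n) stack; ``fitness`` holds each matrix's best
    alignment score (NaN = not yet evaluated).  After ranking, matrices are
    ordered by non-increasing fitness.
    """

    weights: np.ndarray
    n: int
    fitness: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3 or self.weights.shape[1:] != (4, self.n):
            raise ValueError("weights must be (N, 4, n)")
        if self.fitness is None:
            self.fitness = np.full(self.size, np.nan)
        self.fitness = np.asarray(self.fitness, dtype=np.float64)
        if self.fitness.shape != (self.size,):
            raise ValueError("fitness must have one entry per matrix")

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    def matrix(self, i: int) -> WeightMatrix:
        return WeightMatrix(self.weights[i].copy(), self.n)


def _check_period(n: int) -> None:
    if not (N_MIN <= n <= N_MAX):
        raise ValueError(f"period n={n} outside [{N_MIN}, {N_MAX}]")


def build_frequency_matrix(n: int, L1: int = DEFAULT_L1,
                           seed: int | np.random.Generator = 0) -> FrequencyMatrix:
    """Accumulate counts of a random equiprobable sequence vs the 1..n track."""
    _check_period(n)
    if L1 < n:
        raise ValueError("L1 must be at least n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s1 = rng.integers(1, 5, size=L1)
    track = np.arange(L1) % n
    flat = (s1 - 1) * n + track
    counts = np.bincount(flat, minlength=4 * n).reshape(4, n)
    return FrequencyMatrix(counts=counts, n=n, L1=L1)


def normalize_matrix(M: FrequencyMatrix) -> WeightMatrix:
    """Binomial z-scores of counts against the independence expectation."""
    counts = M.counts.astype(float)
    x = counts.sum(axis=1)  # base marginals
    y = counts.sum(axis=0)  # position marginals
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("zero marginal: cannot normalize frequency matrix")
    p = np.outer(x, y) / M.L1**2
    expected = M.L1 * p
    w = (counts - expected) / np.sqrt(expected * (1.0 - p))
    return WeightMatrix(weights=w, n=M.n)


def standardize_matrix(W: WeightMatrix, background: np.ndarray = UNIFORM_BACKGROUND,
                       r2_coeff: float | None = None, r2_exponent: float | None = None,
                       kd_target: float | None = None) -> WeightMatrix:
    """Map W affinely onto the fixed (R², K_d) shell.

    Solves M' = a·W + b·B for the unique a > 0 (and matching b) with
    R²(M') = r2_coeff/n^r2_exponent and K_d(M') = kd_target.
    """
    w = standardize_weights(W.weights, np.asarray(background, float), W.n,
                            r2_coeff, r2_exponent, kd_target)
    return WeightMatrix(weights=w, n=W.n)


def standardize_weights(weights: np.ndarray, p1: np.ndarray, n: int,
                        r2_coeff: float | None = None, r2_exponent: float | None = None,
                        kd_target: float | None = None) -> np.ndarray:
    """Array-level standardisation (see :func:`standardize_matrix`).

    ``None`` targets resolve to the module-level defaults at call time, so
    the package-wide scale can be reconfigured for sensitivity analysis.
    """
    if r2_coeff is None:
        r2_coeff = R2_COEFF
    if r2_exponent is None:
        r2_exponent = R2_EXPONENT
    if kd_target is None:
        kd_target = KD_TARGET
    if not np.isfinite(weights).all():
        raise ValueError("non-finite weights")
    if np.ptp(weights) < 1e-12:
        raise ValueError("degenerate matrix (all cells equal): cannot standardize")
    if abs(p1.sum() - 1.0) > 1e-9:
        raise ValueError("background probabilities must sum to 1")
    target = r2_coeff / float(n) ** r2_exponent

    B = np.outer(p1, np.full(n, 1.0 / n))
    # moments: K_d and R² are linear/quadratic in (a, b)
    k1 = float(weights.sum(axis=1) @ p1 / n)        # K_d of W
    kb = float((p1**2).sum() / n)                   # K_d of B  (= Σ B², see below)
    r1 = float((weights**2).sum())
    c = float((weights * B).sum())
    rb = float((B**2).sum())                        # equals kb for p2 = 1/n
    beta1 = -k1 / kb
    beta0 = kd_target / kb
    qa = r1 + 2.0 * c * beta1 + rb * beta1 * beta1
    qb = 2.0 * beta0 * (c + rb * beta1)
    qc = rb * beta0 * beta0 - target
    if qa <= 1e-12:
        raise ValueError("degenerate matrix (proportional to background): "
                         "cannot standardize")
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0.0:
        raise ValueError("standardization targets unreachable for this matrix")
    a = (-qb + np.sqrt(disc)) / (2.0 * qa)
    if a <= 0.0:
        raise ValueError("no positive scaling solves the standardization constraints")
    b = beta0 + beta1 * a
    return a * weights + b * B


def generate_matrix(n: int, background: np.ndarray = UNIFORM_BACKGROUND,
                    L1: int = DEFAULT_L1,
                    seed: int | np.random.Generator = 0) -> WeightMatrix:
    """One standardized RPWM from a fresh random generating sequence."""
    M = build_frequency_matrix(n, L1=L1, seed=seed)
    return standardize_matrix(normalize_matrix(M), background)


def generate_population(n: int, N: int = 500,
                        background: np.ndarray = UNIFORM_BACKGROUND,
                        L1: int = DEFAULT_L1, seed: int = 0) -> MatrixSet:
    """A population of N independent standardized RPWMs of period n."""
    _check_period(n)
    if N < 4:
        raise ValueError("population must have at least 4 matrices")
    rng = np.random.default_rng(seed)
    weights = np.empty((N, 4, n))
    for i in range(N):
        weights[i] = generate_matrix(n, background, L1=L1, seed=rng).weights
    return MatrixSet(weights=weights, n=n)


# ---------------------------------------------------------------------------
# Serialization: plain TSV, rows a/t/c/g, full float precision.

_ROW_LABELS = ("a", "t", "c", "g")


def write_matrix_tsv(path, W: WeightMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(str(j + 1) for j in range(W.n)) + "\n")
        for label, row in zip(_ROW_LABELS, W.weights):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_tsv(path) -> WeightMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    rows = []
    for label, ln in zip(_ROW_LABELS, lines[1:]):
        parts = ln.split("\t")
        if parts[0] != label:
            raise ValueError(f"expected row {label!r}, found {parts[0]!r}")
        rows.append([float(v) for v in parts[1:]])
    w = np.array(rows)
    return WeightMatrix(weights=w, n=w.shape[1])
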