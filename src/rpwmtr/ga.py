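"""Genetic-algorithm optimisation of the matrix population.

Matrices are the organisms; the fitness of a matrix is its best
affine-gap alignment score against the scanned window.  One cycle:

* mutate ~5% of the matrices (one cell replaced by a uniform draw from
  [−10, 10]), re-standardising afterwards so every organism stays on the
  common (R², K_d) shell;
* breed: drop the worst matrix, pick two distinct parents with
  probability rising linearly with rank (best rank weighted ~2× the
  median), and insert a single-point column-block crossover of the
  parents, re-standardised;
* evaluate any matrix whose weights changed and rank the population by
  fitness (descending vector V).

The running best (mF_max, and its matrix mQ as a snapshot) never
decreases.  Mutation may hit the incumbent best organism — that is what
gives the stopping rule its meaning: the loop stops once the population
best V(1) has stayed *strictly below* the running best mF_max for
``stall_limit`` consecutive cycles (the GA lost its best matrix and
could not recover it), or at ``max_cycles``.  Setting ``protect_best``
exempts the top-ranked matrix from mutation; the stall rule then never
fires and ``max_cycles`` is the budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import pwm
from .align import GapParams, _fmax_kernel
from .pwm import MatrixSet, WeightMatrix, UNIFORM_BACKGROUND
from .seqio import EncodedSequence


@dataclass
class GAConfig:
    population: int = 500
    mutation_fraction: float = 0.05
    mutation_low: float = -10.0
    mutation_high: float = 10.0
    stall_limit: int = 5
    max_cycles: int = 10_000
    protect_best: bool = False
    L1: int = pwm.DEFAULT_L1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mutation_fraction <= 1.0):
            raise ValueError("mutation_fraction must be in (0, 1]")
        if self.stall_limit < 1 or self.max_cycles < 1:
            raise ValueError("stall_limit and max_cycles must be >= 1")
        if self.population < 4:
            raise ValueError("population must be at least 4")


@dataclass
class GAResult:
    best_matrix: WeightMatrix
    best_score: float
    cycles_run: int
    converged: bool
    trace: list = field(default_factory=list)  # (cycle, V1, running best)


def _codes_of(S) -> np.ndarray:
    return (S.codes if isinstance(S, EncodedSequence) else np.asarray(S)).astype(np.int8)


def evaluate_population(S, Q: MatrixSet, gaps: GapParams = GapParams()) -> MatrixSet:
    """Fill the fitness vector and order the set by descending fitness.

    Matrices with a known (non-NaN) fitness are not re-scored: fitness
    depends only on the weights, which are marked stale (NaN) whenever
    they change.  Ranking is stable, so ties keep their insertion order.
    """
    codes = _codes_of(S)
    for i in range(Q.size):
        if math.isnan(Q.fitness[i]):
            Q.fitness[i] = _fmax_kernel(codes, Q.weights[i], Q.n, gaps.d, gaps.e)
    order = np.argsort(-Q.fitness, kind="stable")
    Q.weights = Q.weights[order]
    Q.fitness = Q.fitness[order]
    return Q


def mutate_population(Q: MatrixSet, config: GAConfig,
                      rng: np.random.Generator | None = None,
                      background: np.ndarray = UNIFORM_BACKGROUND) -> MatrixSet:
    """Replace one random cell in ⌈f·N⌉ matrices, then re-standardise them.

    Any matrix may be hit, including the current best, unless
    ``config.protect_best`` is set (then index 0 of the ranked set is
    exempt).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_mut = math.ceil(config.mutation_fraction * Q.size)
    lo = 1 if (config.protect_best and not math.isnan(Q.fitness[0])) else 0
    candidates = np.arange(lo, Q.size)
    chosen = rng.choice(candidates, size=min(n_mut, candidates.size), replace=False)
    for idx in chosen:
        r = rng.integers(4)
        c = rng.integers(Q.n)
        Q.weights[idx, r, c] = rng.uniform(config.mutation_low, config.mutation_high)
        Q.weights[idx] = pwm.standardize_weights(Q.weights[idx], background, Q.n)
        Q.fitness[idx] = np.nan
    return Q


def crossover(parent_a: np.ndarray, parent_b: np.ndarray, n: int,
              rng: np.random.Generator) -> np.ndarray:
    """Single-point column-block crossover: columns 1..c from A, rest from B."""
    c = int(rng.integers(1, n)) if n > 1 else 1
    child = parent_b.copy()
    child[:, :c] = parent_a[:, :c]
    return child


def select_parent_indices(N: int, rng: np.random.Generator) -> tuple[int, int]:
    """Two distinct ranks with linear-ramp weights w(r) ∝ N − r (rank 0 = best)."""
    w = np.arange(N, 0, -1, dtype=float)
    p = w / w.sum()
    a, b = rng.choice(N, size=2, replace=False, p=p)
    return int(a), int(b)


def breed_population(Q: MatrixSet, config: GAConfig,
                     rng: np.random.Generator | None = None,
                     background: np.ndarray = UNIFORM_BACKGROUND) -> MatrixSet:
    """Drop the worst matrix and insert one crossover descendant (size conserved)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    N = Q.size
    a, b = select_parent_indices(N - 1, rng)  # parents among the survivors
    child = crossover(Q.weights[a], Q.weights[b], Q.n, rng)
    child = pwm.standardize_weights(child, background, Q.n)
    Q.weights[N - 1] = child  # ranked set: last slot is the excluded worst
    Q.fitness[N - 1] = np.nan
    return Q


def optimize(S, n: int, background: np.ndarray | None = None,
             gaps: GapParams = GapParams(), config: GAConfig = GAConfig()) -> GAResult:
    """Run the GA for one (window, period) pair and return the best matrix."""
    codes = _codes_of(S)
    if not (pwm.N_MIN <= n <= pwm.N_MAX):
        raise ValueError(f"period n={n} outside [{pwm.N_MIN}, {pwm.N_MAX}]")
    if background is None:
        counts = np.bincount(codes, minlength=5)[1:5]
        background = counts / counts.sum()
    rng = np.random.default_rng(config.seed)
    pop_seed = int(rng.integers(2**31))
    Q = pwm.generate_population(n, N=config.population, background=background,
                                L1=config.L1, seed=pop_seed)
    evaluate_population(codes, Q, gaps)
    best_score = float(Q.fitness[0])
    best_weights = Q.weights[0].copy()
    trace = [(0, float(Q.fitness[0]), best_score)]
    stall = 0
    cycles = 0
    converged = False
    for cycle in range(1, config.max_cycles + 1):
        cycles = cycle
        mutate_population(Q, config, rng, background)
        breed_population(Q, config, rng, background)
        evaluate_population(codes, Q, gaps)
        v1 = float(Q.fitness[0])
        if v1 >= best_score:
            if v1 > best_score:
                best_score = v1
                best_weights = Q.weights[0].copy()
            stall = 0
        else:
            # the population lost its best organism and has not recovered
            stall += 1
            if stall >= config.stall_limit:
                converged = True
                trace.append((cycle, v1, best_score))
                break
        trace.append((cycle, v1, best_score))
    return GAResult(best_matrix=WeightMatrix(best_weights, n),
                    best_score=best_score, cycles_run=cycles,
                    converged=converged, trace=trace)
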