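"""Shuffle-based significance and detection-threshold calibration.

The null model for a window is its own mononucleotide shuffle.  For each
of ``n_shuffles`` composition-preserving permutations of the sequence, a
*fresh random standardized population* is generated and evaluated, and
its best score V(1) is the null draw — the random-matrix stage of the
detector, without genetic-algorithm cycles.  The observed best score
(from the full GA) is then standardised against the shuffle
distribution:

    Z(n) = (mF_max − mean_null) / sd_null.

Z therefore measures how far the optimised score of the real sequence
rises above what random matrices achieve on randomized sequence; it
grows both with repeat strength and with GA effort, so Z values are
comparable only at a fixed GA configuration.  ``null_mode="optimize"``
instead re-runs the full GA on every shuffle (an apples-to-apples
permutation test; ~population·cycles times more expensive, and the
resulting Z is near-normal under the null).

The detection threshold F0 is calibrated empirically: repeats are called
on the real sequences and on their shuffles, and F0 is the smallest grid
value for which the false discovery rate T_rand/(T_rand + T_real) drops
below the target (0.01 by default).  F0 is budget-specific — both signal
and null scores shift with the GA effort — so a scaled-down run must
recalibrate rather than reuse a threshold calibrated at another budget.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .align import GapParams
from .ga import GAConfig, evaluate_population, optimize
from .pwm import generate_population
from .scan import ScanConfig, find_local_maxima, scan_sequence
from .seqio import EncodedSequence, shuffle_sequence

DEFAULT_SHUFFLES = 200


@dataclass
class ZResult:
    z: float
    n_shuffles: int
    mean_null: float
    var_null: float
    observed_mfmax: float
    null_scores: np.ndarray


@dataclass
class FDRCalibration:
    f0: float
    t_rand: int
    t_real: int
    fdr: float


def population_best_score(S: EncodedSequence, n: int,
                          ga_config: GAConfig = GAConfig(),
                          gaps: GapParams = GapParams(),
                          seed: int = 0) -> float:
    """V(1) of a fresh random standardized population — no GA cycles."""
    codes = S.codes
    counts = np.bincount(codes, minlength=5)[1:5]
    background = counts / counts.sum()
    Q = generate_population(n, N=ga_config.population, background=background,
                            L1=ga_config.L1, seed=seed)
    evaluate_population(codes, Q, gaps)
    return float(Q.fitness[0])


def z_statistic(S: EncodedSequence, n: int,
                ga_config: GAConfig = GAConfig(),
                gaps: GapParams = GapParams(),
                n_shuffles: int = DEFAULT_SHUFFLES,
                seed: int = 0,
                null_mode: str = "population") -> ZResult:
    """Shuffle-null Z of the best GA score for one (sequence, period) pair.

    The variance is the unbiased sample variance of the shuffle scores.
    """
    if null_mode not in ("population", "optimize"):
        raise ValueError("null_mode must be 'population' or 'optimize'")
    root = np.random.SeedSequence(entropy=seed, spawn_key=(101, n))
    seeds = root.generate_state(n_shuffles + 1) % 2**31
    observed = optimize(S, n, gaps=gaps,
                        config=dc_replace(ga_config, seed=int(seeds[0])))
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = shuffle_sequence(S, int(seeds[i + 1]))
        if null_mode == "population":
            null[i] = population_best_score(shuffled, n, ga_config, gaps,
                                            seed=int(seeds[i + 1]))
        else:
            res = optimize(shuffled, n, gaps=gaps,
                           config=dc_replace(ga_config, seed=int(seeds[i + 1])))
            null[i] = res.best_score
    mean_null = float(null.mean())
    var_null = float(null.var(ddof=1))
    if var_null <= 0.0:
        raise ValueError("degenerate shuffle null: zero variance "
                         f"(all {n_shuffles} shuffle scores identical)")
    z = (observed.best_score - mean_null) / np.sqrt(var_null)
    return ZResult(z=float(z), n_shuffles=n_shuffles, mean_null=mean_null,
                   var_null=var_null, observed_mfmax=observed.best_score,
                   null_scores=null)


def calibrate_threshold(sequences: list[EncodedSequence],
                        config: ScanConfig = ScanConfig(),
                        target_fdr: float = 0.01,
                        grid: np.ndarray | None = None,
                        seed: int = 0) -> FDRCalibration:
    """Smallest F0 on the grid with FDR = T_rand/(T_rand + T_real) < target.

    Each sequence is shuffled once (with a seed derived from ``seed``);
    regions are counted above every candidate threshold.
    """
    if not sequences:
        raise ValueError("at least one sequence required")
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must be in (0, 1)")
    if grid is None:
        grid = np.arange(200.0, 801.0, 10.0)
    real_scores: list[float] = []
    rand_scores: list[float] = []
    for i, seq in enumerate(sequences):
        res = scan_sequence(seq, config)
        real_scores.extend(r.mfmax for r in find_local_maxima(res, f0=0.0))
        shuf = shuffle_sequence(seq, seed + 7919 * (i + 1))
        res_s = scan_sequence(shuf, config)
        rand_scores.extend(r.mfmax for r in find_local_maxima(res_s, f0=0.0))
    real = np.asarray(real_scores)
    rand = np.asarray(rand_scores)
    best: FDRCalibration | None = None
    for f0 in grid:
        t_real = int((real > f0).sum())
        t_rand = int((rand > f0).sum())
        total = t_rand + t_real
        fdr = t_rand / total if total > 0 else 0.0
        cal = FDRCalibration(f0=float(f0), t_rand=t_rand, t_real=t_real, fdr=fdr)
        if best is None or cal.fdr < best.fdr:
            best = cal
        if fdr < target_fdr:
            return cal
    raise ValueError("target FDR unreachable on the grid; best achievable: "
                     f"F0={best.f0}, FDR={best.fdr:.4f} "
                     f"(T_rand={best.t_rand}, T_real={best.t_real})")
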