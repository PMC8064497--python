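"""Genome scanning: windows × periods → score surface → called regions.

A window of length L (default 650) slides along the sequence at a fixed
step (default 10).  Windows with indel-free triplet periodicity are
skipped (their surface cells stay 0).  Every remaining (window k, period
n) cell runs its own GA with a seed derived deterministically from
(global seed, sequence id, k, n), so cells may be computed in any order —
or in parallel — with identical results.

Region calling is two-dimensional local-maxima selection on the
mF_max(k, n) surface:

1. along k, within each period, a cell survives only if it strictly
   exceeds every competitor within ±``neighborhood`` grid steps
   (competitors are zeroed);
2. across periods, a surviving cell must also strictly exceed every
   survivor at any other period within the same k-neighborhood;
3. only cells with mF_max > F0 are emitted.

The winner's alignment is traced back and its window-relative span is
mapped to sequence coordinates (0-based half-open internally).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .align import AlignmentResult, GapParams, traceback_alignment
from .ga import GAConfig, GAResult, optimize
from .pwm import WeightMatrix
from .seqio import EncodedSequence
from .triplet import DEFAULT_THRESHOLD, passes_triplet_filter, triplet_statistic


@dataclass
class ScanConfig:
    window_length: int = 650
    step: int = 10
    n_min: int = 2
    n_max: int = 50
    neighborhood: int = 64          # in k-grid units
    f0: float = 390.0
    triplet_threshold: float = DEFAULT_THRESHOLD
    ga: GAConfig = field(default_factory=GAConfig)
    gaps: GapParams = field(default_factory=GapParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not (2 <= self.n_min <= self.n_max <= 50):
            raise ValueError("period range must satisfy 2 <= n_min <= n_max <= 50")
        if self.window_length <= self.n_max:
            raise ValueError("window must be longer than the largest period")


@dataclass
class TRRegion:
    """A called tandem repeat (coordinates 0-based half-open)."""

    seq_id: str
    start: int
    end: int
    n: int
    mfmax: float
    matrix: WeightMatrix
    alignment: AlignmentResult
    window_start: int
    z: float | None = None

    @property
    def consensus(self) -> str:
        return self.matrix.consensus()

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ScanResult:
    seq: EncodedSequence
    config: ScanConfig
    k_grid: np.ndarray              # window start positions (0-based)
    n_values: np.ndarray
    surface: np.ndarray             # (len(n_values), len(k_grid)) of mF_max
    window_passed: np.ndarray       # triplet-filter mask per window
    cache: dict                     # (k, n) -> GAResult


def cell_seed(global_seed: int, seq_id: str, k: int, n: int) -> int:
    """Deterministic per-cell GA seed; order- and thread-independent."""
    tag = zlib.crc32(seq_id.encode())
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(tag, k, n))
    return int(ss.generate_state(1)[0]) % 2**31


def scan_sequence(chrom: EncodedSequence, config: ScanConfig = ScanConfig()) -> ScanResult:
    """Fill the mF_max(k, n) surface for one sequence."""
    L = config.window_length
    if len(chrom) < L:
        raise ValueError(f"sequence length {len(chrom)} < window length {L}")
    k_grid = np.arange(0, len(chrom) - L + 1, config.step)
    n_values = np.arange(config.n_min, config.n_max + 1)
    surface = np.zeros((n_values.size, k_grid.size))
    window_passed = np.zeros(k_grid.size, dtype=bool)
    cache: dict[tuple[int, int], GAResult] = {}
    for ki, k in enumerate(k_grid):
        window = chrom.window(int(k), L)
        if not passes_triplet_filter(triplet_statistic(window),
                                     config.triplet_threshold):
            continue
        window_passed[ki] = True
        counts = np.bincount(window, minlength=5)[1:5]
        background = counts / counts.sum()
        for ni, n in enumerate(n_values):
            ga_cfg = dc_replace(config.ga,
                                seed=cell_seed(config.seed, chrom.id, int(k), int(n)))
            result = optimize(window, int(n), background=background,
                              gaps=config.gaps, config=ga_cfg)
            surface[ni, ki] = result.best_score
            cache[(int(k), int(n))] = result
    return ScanResult(seq=chrom, config=config, k_grid=k_grid,
                      n_values=n_values, surface=surface,
                      window_passed=window_passed, cache=cache)


def _local_maxima_1d(row: np.ndarray, radius: int) -> np.ndarray:
    """Indices of cells strictly greater than all others within ±radius."""
    keep = []
    for i, v in enumerate(row):
        if v <= 0.0:
            continue
        lo = max(0, i - radius)
        hi = min(row.size, i + radius + 1)
        neigh = np.delete(row[lo:hi], i - lo)
        if neigh.size == 0 or v > neigh.max():
            keep.append(i)
    return np.asarray(keep, dtype=int)


def find_local_maxima(result: ScanResult, f0: float | None = None) -> list[TRRegion]:
    """Two-stage local-maxima selection; emit regions above F0."""
    config = result.config
    if f0 is None:
        f0 = config.f0
    radius = config.neighborhood
    # stage 1: per-period maxima along k (non-maxima zeroed)
    survivors: list[tuple[int, int, float]] = []  # (ni, ki, value)
    for ni in range(result.n_values.size):
        row = result.surface[ni]
        for ki in _local_maxima_1d(row, radius):
            survivors.append((ni, ki, float(row[ki])))
    # stage 2: across periods within the same k-neighborhood
    regions: list[TRRegion] = []
    for ni, ki, v in survivors:
        if v <= f0:
            continue
        dominated = False
        for nj, kj, u in survivors:
            if nj != ni and abs(kj - ki) <= radius and u >= v:
                dominated = True
                break
        if dominated:
            continue
        k = int(result.k_grid[ki])
        n = int(result.n_values[ni])
        ga_res = result.cache[(k, n)]
        window = result.seq.window(k, config.window_length)
        aln = traceback_alignment(window, ga_res.best_matrix, config.gaps)
        regions.append(TRRegion(seq_id=result.seq.id,
                                start=k + aln.i0 - 1, end=k + aln.im,
                                n=n, mfmax=v, matrix=ga_res.best_matrix,
                                alignment=aln, window_start=k))
    regions.sort(key=lambda r: (r.start, r.n))
    return regions


def call_repeats(chrom: EncodedSequence,
                 config: ScanConfig = ScanConfig()) -> list[TRRegion]:
    """Scan one sequence and return called repeat regions, sorted by start."""
    return find_local_maxima(scan_sequence(chrom, config))
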