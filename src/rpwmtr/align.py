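"""Affine-gap profile alignment: the GA's fitness kernel.

A window S of length L is aligned against the tandem extension of a 4×n
weight matrix — conceptually the position track S2 = 1,2,…,n,1,2,… of
length L, with substitution score q(s(i), s2(j)) read from matrix column
s2(j).  Three L×L state matrices are filled:

    F(i,j)  = max{F, Fx, Fy}(i−1,j−1) + q(s(i), s2(j))
    Fx(i,j) = max{F(i−1,j) − d, Fx(i−1,j) − e}      (gap in the profile)
    Fy(i,j) = max{F(i,j−1) − d, Fy(i,j−1) − e}      (gap in the window)

with free-start boundaries F(0,·) = F(·,0) = 0, gap states −∞ on the
boundaries, and the optimum taken over the far edges F(L,·) and F(·,L)
only.  Note there is no interior max(0, ·): this is a free-end variant,
not textbook Smith–Waterman, and gap states rejoin the match state only
through a diagonal step.

``brute_force_align`` is an exhaustive enumeration over all monotone
affine-gap paths with the same conventions; it exists purely as a test
oracle and is guarded to tiny windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .pwm import WeightMatrix
from .seqio import EncodedSequence

_NEG = -1e300


@dataclass
class GapParams:
    """Affine gap costs: d to open an indel, e to extend it."""

    d: float = 25.0
    e: float = 6.0

    def __post_init__(self) -> None:
        if not (self.d >= self.e >= 0.0):
            raise ValueError("gap costs must satisfy d >= e >= 0")


@dataclass
class AlignmentResult:
    """Best score with the traced alignment.

    ``pairs`` lists (window position | None, profile position | None),
    1-based; ``i0``/``im`` bound the aligned window span (1-based
    inclusive), ``j0``/``jm`` the profile span.
    """

    fmax: float
    i0: int
    im: int
    j0: int
    jm: int
    pairs: list = field(default_factory=list)


def _codes_of(S) -> np.ndarray:
    codes = S.codes if isinstance(S, EncodedSequence) else np.asarray(S)
    return codes.astype(np.int8)


def _check(codes: np.ndarray, W: WeightMatrix) -> None:
    if codes.size < W.n:
        raise ValueError(f"window length {codes.size} < period {W.n}")
    if not np.isfinite(W.weights).all():
        raise ValueError("non-finite weight matrix")


@njit(cache=True, fastmath=False)
def _fmax_kernel(codes, weights, n, d, e):  # pragma: no cover - jitted
    L = codes.shape[0]
    Fp = np.zeros(L + 1)
    Fxp = np.full(L + 1, _NEG)
    Fyp = np.full(L + 1, _NEG)
    Fc = np.empty(L + 1)
    Fxc = np.empty(L + 1)
    Fyc = np.empty(L + 1)
    best = _NEG
    jmod = np.empty(L, np.int64)
    for j in range(L):
        jmod[j] = j % n
    for i in range(1, L + 1):
        Fc[0] = 0.0
        Fxc[0] = _NEG
        Fyc[0] = _NEG
        row = weights[codes[i - 1] - 1]
        for j in range(1, L + 1):
            q = row[jmod[j - 1]]
            f = Fp[j - 1]
            if Fxp[j - 1] > f:
                f = Fxp[j - 1]
            if Fyp[j - 1] > f:
                f = Fyp[j - 1]
            Fc[j] = f + q
            fx = Fp[j] - d
            fx2 = Fxp[j] - e
            Fxc[j] = fx if fx > fx2 else fx2
            fy = Fc[j - 1] - d
            fy2 = Fyc[j - 1] - e
            Fyc[j] = fy if fy > fy2 else fy2
        if Fc[L] > best:
            best = Fc[L]
        Fp, Fc = Fc, Fp
        Fxp, Fxc = Fxc, Fxp
        Fyp, Fyc = Fyc, Fyp
    for j in range(1, L + 1):
        if Fp[j] > best:
            best = Fp[j]
    return best


@njit(cache=True, fastmath=False)
def _full_kernel(codes, weights, n, d, e):  # pragma: no cover - jitted
    """Full F/Fx/Fy tables plus back-pointers for traceback."""
    L = codes.shape[0]
    F = np.zeros((L + 1, L + 1))
    Fx = np.full((L + 1, L + 1), _NEG)
    Fy = np.full((L + 1, L + 1), _NEG)
    # predecessor state of each cell: for F, which of F/Fx/Fy fed the
    # diagonal (0/1/2); for Fx and Fy, whether the gap opened (0) or
    # extended (1/2).
    bF = np.zeros((L + 1, L + 1), np.int8)
    bX = np.zeros((L + 1, L + 1), np.int8)
    bY = np.zeros((L + 1, L + 1), np.int8)
    for i in range(1, L + 1):
        row = weights[codes[i - 1] - 1]
        for j in range(1, L + 1):
            q = row[(j - 1) % n]
            f = F[i - 1, j - 1]
            s = 0
            if Fx[i - 1, j - 1] > f:
                f = Fx[i - 1, j - 1]
                s = 1
            if Fy[i - 1, j - 1] > f:
                f = Fy[i - 1, j - 1]
                s = 2
            F[i, j] = f + q
            bF[i, j] = s
            fx = F[i - 1, j] - d
            fx2 = Fx[i - 1, j] - e
            if fx >= fx2:
                Fx[i, j] = fx
                bX[i, j] = 0
            else:
                Fx[i, j] = fx2
                bX[i, j] = 1
            fy = F[i, j - 1] - d
            fy2 = Fy[i, j - 1] - e
            if fy >= fy2:
                Fy[i, j] = fy
                bY[i, j] = 0
            else:
                Fy[i, j] = fy2
                bY[i, j] = 2
    return F, Fx, Fy, bF, bX, bY


def score_profile_alignment(S, W: WeightMatrix, gaps: GapParams = GapParams()) -> float:
    """Best far-edge score of the window against the tandem-extended matrix."""
    codes = _codes_of(S)
    _check(codes, W)
    return float(_fmax_kernel(codes, W.weights, W.n, gaps.d, gaps.e))


def traceback_alignment(S, W: WeightMatrix,
                        gaps: GapParams = GapParams()) -> AlignmentResult:
    """Best alignment with its path, traced back to the first zero-score cell."""
    codes = _codes_of(S)
    _check(codes, W)
    L = codes.size
    F, Fx, Fy, bF, bX, bY = _full_kernel(codes, W.weights, W.n, gaps.d, gaps.e)
    # best terminal on the far edges; scan order makes ties deterministic
    bi, bj = L, 1
    for j in range(1, L + 1):
        if F[L, j] > F[bi, bj]:
            bi, bj = L, j
    for i in range(1, L + 1):
        if F[i, L] > F[bi, bj]:
            bi, bj = i, L
    fmax = float(F[bi, bj])

    pairs: list[tuple[int | None, int | None]] = []
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            if i == 0 or j == 0 or F[i, j] == 0.0:
                break
            pairs.append((i, j))
            state = int(bF[i, j])
            i -= 1
            j -= 1
        elif state == 1:  # gap in the profile: consumes window position i
            pairs.append((i, None))
            nxt = int(bX[i, j])
            i -= 1
            state = 0 if nxt == 0 else 1
        else:  # gap in the window: consumes profile position j
            pairs.append((None, j))
            nxt = int(bY[i, j])
            j -= 1
            state = 0 if nxt == 0 else 2
    pairs.reverse()
    wi = [p[0] for p in pairs if p[0] is not None]
    pj = [p[1] for p in pairs if p[1] is not None]
    if not wi:  # empty alignment (e.g. all-zero matrix): degenerate span
        return AlignmentResult(fmax=fmax, i0=bi, im=bi, j0=bj, jm=bj, pairs=[])
    return AlignmentResult(fmax=fmax, i0=min(wi), im=max(wi),
                           j0=min(pj), jm=max(pj), pairs=pairs)


def score_from_pairs(pairs, codes, W: WeightMatrix, gaps: GapParams) -> float:
    """Recompute the score of a traced path (consistency checks in tests)."""
    codes = _codes_of(codes)
    total = 0.0
    prev = None  # None | "D" | "X" | "Y"
    for wi, pj in pairs:
        if wi is not None and pj is not None:
            total += W.weights[codes[wi - 1] - 1, (pj - 1) % W.n]
            prev = "D"
        elif wi is not None:
            total -= gaps.e if prev == "X" else gaps.d
            prev = "X"
        else:
            total -= gaps.e if prev == "Y" else gaps.d
            prev = "Y"
    return total


# ---------------------------------------------------------------------------
# Exhaustive oracle

MAX_BRUTE_LEN = 12


def brute_force_align(S, W: WeightMatrix, gaps: GapParams = GapParams()) -> float:
    """Exact optimum by enumerating every monotone affine-gap path.

    Same conventions as the DP: free start on the zero boundaries, gap
    states open with −d from a match and extend with −e, no direct
    gap-to-gap turn, and the path must end in the match state on a far
    edge.  Exponential; guarded to windows of length ≤ 12.
    """
    codes = _codes_of(S)
    _check(codes, W)
    L = codes.size
    if L > MAX_BRUTE_LEN:
        raise ValueError(f"brute force limited to windows of length <= {MAX_BRUTE_LEN}")
    n = W.n
    weights = W.weights
    d, e = gaps.d, gaps.e
    best = [-np.inf]

    def q(i: int, j: int) -> float:
        return weights[codes[i - 1] - 1, (j - 1) % n]

    def explore(i: int, j: int, state: int, score: float) -> None:
        if state == 0 and i >= 1 and j >= 1 and (i == L or j == L):
            if score > best[0]:
                best[0] = score
            return  # far edge reached in match state: no further terminal possible
        if i < L and j < L:
            explore(i + 1, j + 1, 0, score + q(i + 1, j + 1))
        # gap states do not exist on the zero boundaries (they start at -inf)
        if i < L and j >= 1 and state != 2:
            explore(i + 1, j, 1, score - (d if state == 0 else e))
        if j < L and i >= 1 and state != 1:
            explore(i, j + 1, 2, score - (d if state == 0 else e))

    for i0 in range(L):
        explore(i0, 0, 0, 0.0)
    for j0 in range(1, L):
        explore(0, j0, 0, 0.0)
    return float(best[0])
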