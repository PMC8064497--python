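"""Triplet-periodicity filter.

Most coding sequence carries strong period-3 base composition without
indels.  Such windows would flood a tandem-repeat scan, so they are
excluded up front with a mutual-information statistic: the window is laid
alongside the frame track 1,2,3,1,2,3,… and base counts are accumulated in
a 3×4 table m3(phase, base).  The G-statistic

    2I = 2 [ Σ m3·ln m3 − Σ x·ln x − Σ y·ln y + L·ln L ]

(with 0·ln 0 ≡ 0) is asymptotically χ² with (3−1)(4−1) = 6 degrees of
freedom under phase/base independence.  It is mapped to the normal scale
via x₃ = sqrt(4I) − sqrt(2·6 − 1); windows with x₃ ≥ 3 are skipped.

Triplet repeats *with* indels do not trip this filter (the indel shifts
the frame) and are found by the main scan at n = 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .seqio import EncodedSequence

#: minimum window length for a meaningful χ²(6) approximation
MIN_WINDOW = 30

#: default normal-scale cutoff ("x₃ < 3" keeps the window)
DEFAULT_THRESHOLD = 3.0

_SQRT11 = np.sqrt(11.0)


@dataclass
class TripletStat:
    m3: np.ndarray      # (3, 4) counts
    two_I: float
    x3: float


def triplet_statistic(window: EncodedSequence | np.ndarray) -> TripletStat:
    """Mutual-information statistic of the phase×base table of a window."""
    codes = window.codes if isinstance(window, EncodedSequence) else np.asarray(window)
    L = codes.size
    if L < MIN_WINDOW:
        raise ValueError(f"window length {L} < {MIN_WINDOW}")
    phase = np.arange(L) % 3
    m3 = np.bincount(phase * 4 + (codes - 1), minlength=12).reshape(3, 4).astype(float)
    two_I = _two_I_from_counts(m3)
    x3 = float(np.sqrt(2.0 * two_I) - _SQRT11)
    return TripletStat(m3=m3, two_I=two_I, x3=x3)


def _two_I_from_counts(m3: np.ndarray) -> float:
    x = m3.sum(axis=1)
    y = m3.sum(axis=0)
    L = m3.sum()
    s = xlogy(m3, m3).sum() - xlogy(x, x).sum() - xlogy(y, y).sum() + xlogy(L, L)
    # clamp tiny negative round-off: 2I is a KL divergence, hence >= 0
    return max(float(2.0 * s), 0.0)


def passes_triplet_filter(stat: TripletStat, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff the window is free of indel-free triplet periodicity (x₃ < threshold)."""
    return stat.x3 < threshold
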