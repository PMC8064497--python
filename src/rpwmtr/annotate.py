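"""Overlap of called repeats with annotation features.

A repeat region counts as intersecting a feature class when at least 80%
of the *region's* length is covered by the union of features on the same
sequence.  Significance of the observed intersection count C is assessed
by Monte-Carlo relocation: features are repositioned uniformly at random
within their sequence (lengths preserved), the count is re-measured per
shuffle, and

    X = (C − C̄) / sqrt(D(C))

standardises the observation against the relocation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Feature:
    """An annotation interval (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    class_label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("feature must have start < end")


@dataclass
class OverlapResult:
    c: int
    c_bar: float
    d_c: float
    x_stat: float

    @classmethod
    def from_moments(cls, c: int, c_bar: float, d_c: float) -> "OverlapResult":
        if d_c <= 0.0:
            raise ValueError("shuffle variance must be positive")
        return cls(c=c, c_bar=c_bar, d_c=d_c,
                   x_stat=float((c - c_bar) / np.sqrt(d_c)))


def read_features(path) -> list[Feature]:
    """Read features from BED (name column = class) or a seq/start/end/class TSV."""
    out: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed feature line: {line!r}")
            label = parts[3] if len(parts) > 3 else ""
            out.append(Feature(seq_id=parts[0], start=int(parts[1]),
                               end=int(parts[2]), class_label=label))
    return out


def _merged_by_seq(features) -> dict[str, np.ndarray]:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_seq.setdefault(f.seq_id, []).append((f.start, f.end))
    merged: dict[str, np.ndarray] = {}
    for sid, ivals in by_seq.items():
        ivals.sort()
        out = []
        cs, ce = ivals[0]
        for s, e in ivals[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((cs, ce))
                cs, ce = s, e
        out.append((cs, ce))
        merged[sid] = np.asarray(out)
    return merged


def _span_of(region) -> tuple[str, int, int]:
    if hasattr(region, "seq_id"):
        return region.seq_id, region.start, region.end
    return region  # (seq_id, start, end) tuple


def overlap_count(regions, features, min_fraction: float = 0.8) -> int:
    """Regions whose span is ≥ min_fraction covered by the feature union."""
    merged = _merged_by_seq(features)
    count = 0
    for region in regions:
        sid, start, end = _span_of(region)
        ivals = merged.get(sid)
        if ivals is None:
            continue
        covered = 0
        # merged intervals are sorted and disjoint; clip each to the region
        lo = np.searchsorted(ivals[:, 1], start, side="right")
        for s, e in ivals[lo:]:
            if s >= end:
                break
            covered += min(end, e) - max(start, s)
        if covered / (end - start) >= min_fraction:
            count += 1
    return count


def permutation_x_statistic(regions, features, seq_lengths: dict,
                            n_shuffles: int = 100, seed: int = 0,
                            min_fraction: float = 0.8) -> OverlapResult:
    """Monte-Carlo X statistic of region–feature colocation.

    Features are relocated uniformly and independently within their own
    sequence, never extending past its end; overlaps among relocated
    features are allowed.
    """
    if n_shuffles < 30:
        raise ValueError("need at least 30 shuffles for stable moments")
    c = overlap_count(regions, features, min_fraction)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_shuffles)
    feats = list(features)
    for s in range(n_shuffles):
        moved = []
        for f in feats:
            L = seq_lengths[f.seq_id]
            flen = f.end - f.start
            if flen > L:
                raise ValueError(f"feature longer than sequence {f.seq_id}")
            start = int(rng.integers(0, L - flen + 1))
            moved.append(Feature(f.seq_id, start, start + flen, f.class_label))
        counts[s] = overlap_count(regions, moved, min_fraction)
    c_bar = float(counts.mean())
    d_c = float(counts.var(ddof=1))
    if d_c <= 0.0:
        raise ValueError("zero shuffle variance: null counts are degenerate")
    return OverlapResult(c=c, c_bar=c_bar, d_c=d_c,
                         x_stat=float((c - c_bar) / np.sqrt(d_c)))


def per_class_table(regions, features, seq_lengths: dict,
                    n_shuffles: int = 100, seed: int = 0,
                    min_fraction: float = 0.8) -> pd.DataFrame:
    """Observed/expected/X per feature class (one Monte-Carlo run per class)."""
    classes = sorted({f.class_label for f in features})
    rows = []
    for i, cls in enumerate(classes):
        sub = [f for f in features if f.class_label == cls]
        res = permutation_x_statistic(regions, sub, seq_lengths,
                                      n_shuffles=n_shuffles, seed=seed + i,
                                      min_fraction=min_fraction)
        rows.append({"class": cls, "observed": res.c, "expected": res.c_bar,
                     "X": res.x_stat})
    return pd.DataFrame(rows)
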