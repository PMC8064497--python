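"""Synthetic tandem-repeat benchmarks and detection-power experiments.

A benchmark sequence is a random repeat unit copied in tandem, degraded
by point substitutions and single-base indels, optionally flanked by
random sequence:

* the 30-nt benchmark: a 3000-nt core of 100 copies of a 30-nt unit,
  50 insertions + 50 deletions, no flanks — used for the Z-vs-divergence
  curve;
* the 6-nt benchmark: a 600-nt core of 100 copies of a 6-nt unit,
  5 insertions + 5 deletions, 300-nt flanks on both sides (1200 nt
  total) — used for the detection-rate curve Y(x).

Substitution *draws* pick a uniform core position and replace it with a
uniform base (so ~25% of draws are silent); every draw is counted in the
per-position vector y(k), from which the divergence measure x — the
average number of substitutions per nucleotide between any two repeat
copies — is computed over ordered copy pairs:

    x = Σ_{i≠j} (u_i + u_j) / (unit_length · P),   P = copies·(copies−1)

with u_i the draw count inside copy i; this collapses to
2·Σy / (unit_length · copies).  Indels are applied after substitutions,
at uniform positions without replacement, and the planted unit spans are
remapped through them to give the truth set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .align import GapParams
from .ga import GAConfig
from .scan import ScanConfig, TRRegion, call_repeats
from .seqio import EncodedSequence
from .stats import ZResult, z_statistic


@dataclass
class PlantedRepeatSpec:
    unit_length: int
    copies: int = 100
    n_insertions: int = 0
    n_deletions: int = 0
    n_substitutions: int = 0
    flank_length: int = 0
    seed: int = 0

    @property
    def core_length(self) -> int:
        return self.unit_length * self.copies


def thirty_nt_spec(n_substitutions: int, seed: int = 0) -> PlantedRepeatSpec:
    """The 30-nt benchmark: 100×30 nt core, 50+50 indels, no flanks."""
    return PlantedRepeatSpec(unit_length=30, copies=100, n_insertions=50,
                             n_deletions=50, n_substitutions=n_substitutions,
                             flank_length=0, seed=seed)


def six_nt_spec(n_substitutions: int, seed: int = 0) -> PlantedRepeatSpec:
    """The 6-nt benchmark: 100×6 nt core, 5+5 indels, 300-nt flanks."""
    return PlantedRepeatSpec(unit_length=6, copies=100, n_insertions=5,
                             n_deletions=5, n_substitutions=n_substitutions,
                             flank_length=300, seed=seed)


@dataclass
class MutationVector:
    """Per-position substitution-draw counts over the pre-indel core."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if (self.y < 0).any():
            raise ValueError("negative substitution count")


@dataclass
class TruthSet:
    """Planted unit spans in final (post-indel, flank-shifted) coordinates."""

    spans: list  # [(start, end), ...] 0-based half-open, ordered
    period: int


def subs_for_load(x: float, spec: PlantedRepeatSpec) -> int:
    """Substitution draws needed for divergence x (inverse of the closed form)."""
    return round(x * spec.unit_length * spec.copies / 2.0)


def mutation_load(y: MutationVector, spec: PlantedRepeatSpec) -> float:
    """Divergence x from the per-position draw counts (ordered-pair form)."""
    u = y.y.reshape(spec.copies, spec.unit_length).sum(axis=1)
    pairs = spec.copies * (spec.copies - 1)
    # Σ_{i≠j} (u_i + u_j) = 2 (copies − 1) Σu
    return float(2.0 * (spec.copies - 1) * u.sum() / (spec.unit_length * pairs))


def plant_tandem_repeats(spec: PlantedRepeatSpec
                         ) -> tuple[EncodedSequence, MutationVector, TruthSet]:
    """Build a benchmark sequence with its mutation vector and truth spans."""
    core_len = spec.core_length
    if spec.n_deletions >= core_len:
        raise ValueError("cannot delete more bases than the core contains")
    rng = np.random.default_rng(spec.seed)
    unit = rng.integers(1, 5, size=spec.unit_length)
    core = np.tile(unit, spec.copies)

    y = np.zeros(core_len, dtype=np.int64)
    if spec.n_substitutions:
        pos = rng.integers(0, core_len, size=spec.n_substitutions)
        base = rng.integers(1, 5, size=spec.n_substitutions)
        core[pos] = base  # repeated positions resolve to the last draw
        y = np.bincount(pos, minlength=core_len)

    del_pos = rng.choice(core_len, size=spec.n_deletions, replace=False)
    ins_pos = rng.choice(core_len + 1, size=spec.n_insertions, replace=False)
    ins_base = rng.integers(1, 5, size=spec.n_insertions)

    deleted = np.zeros(core_len, dtype=bool)
    deleted[del_pos] = True
    ins_at: dict[int, list[int]] = {}
    for p, b in zip(ins_pos, ins_base):
        ins_at.setdefault(int(p), []).append(int(b))

    edited: list[int] = []
    new_of = np.empty(core_len + 1, dtype=np.int64)  # old boundary -> new coord
    for p in range(core_len + 1):
        new_of[p] = len(edited)
        if p in ins_at:
            edited.extend(ins_at[p])
        if p < core_len and not deleted[p]:
            edited.append(int(core[p]))
    # insertions sit before their old position, so re-read boundaries after them
    for p in ins_at:
        new_of[p] += len(ins_at[p])
    new_of[core_len] = len(edited)

    flank_l = rng.integers(1, 5, size=spec.flank_length)
    flank_r = rng.integers(1, 5, size=spec.flank_length)
    codes = np.concatenate([flank_l, np.asarray(edited), flank_r])

    spans = []
    off = spec.flank_length
    for u in range(spec.copies):
        a = int(new_of[u * spec.unit_length]) + off
        b = int(new_of[(u + 1) * spec.unit_length]) + off
        if b > a:  # a fully deleted unit leaves no span
            spans.append((a, b))
    seq = EncodedSequence(id=f"planted_u{spec.unit_length}_s{spec.n_substitutions}",
                          codes=codes)
    return seq, MutationVector(y=y), TruthSet(spans=spans, period=spec.unit_length)


# ---------------------------------------------------------------------------
# Experiments


def central_window(seq: EncodedSequence, length: int = 650) -> EncodedSequence:
    """The centred window used when a benchmark exceeds the scan window."""
    if len(seq) <= length:
        return seq
    start = (len(seq) - length) // 2
    return EncodedSequence(id=seq.id, codes=seq.window(start, length),
                           offset=start)


def z_vs_x_experiment(ladder: list[PlantedRepeatSpec],
                      ga_config: GAConfig = GAConfig(),
                      gaps: GapParams = GapParams(),
                      window_length: int = 650,
                      n_shuffles: int = 200,
                      seed: int = 0) -> pd.DataFrame:
    """The Z-versus-divergence curve: one row (x, Z) per ladder sequence."""
    rows = []
    for spec in ladder:
        seq, y, truth = plant_tandem_repeats(spec)
        x = mutation_load(y, spec)
        win = central_window(seq, window_length)
        zr = z_statistic(win, spec.unit_length, ga_config=ga_config, gaps=gaps,
                         n_shuffles=n_shuffles, seed=seed + spec.seed)
        rows.append({"x": x, "z": zr.z, "observed": zr.observed_mfmax,
                     "mean_null": zr.mean_null, "var_null": zr.var_null})
    return pd.DataFrame(rows)


def unit_detection_fraction(regions: list[TRRegion], truth: TruthSet,
                            min_coverage: float = 0.5) -> float:
    """Fraction of planted units ≥ min_coverage covered by regions of the
    exact planted period (harmonics count as misses)."""
    hits = 0
    correct = [(r.start, r.end) for r in regions if r.n == truth.period]
    for a, b in truth.spans:
        covered = sum(max(0, min(b, e) - max(a, s)) for s, e in correct)
        if covered / (b - a) >= min_coverage:
            hits += 1
    return hits / len(truth.spans)


def detection_rate_experiment(specs: list[PlantedRepeatSpec],
                              scan_config: ScanConfig,
                              replicates: int = 5,
                              seed: int = 0) -> pd.DataFrame:
    """Detection-rate curve Y(x): mean detected-unit fraction per spec.

    Each replicate redraws the benchmark (unit, mutations, flanks) with a
    derived seed and re-runs the full scan.
    """
    rows = []
    for si, spec in enumerate(specs):
        ys = []
        xs = []
        for rep in range(replicates):
            rep_seed = int(np.random.SeedSequence(
                entropy=seed, spawn_key=(si, rep)).generate_state(1)[0] % 2**31)
            rspec = dc_replace(spec, seed=rep_seed)
            seq, y, truth = plant_tandem_repeats(rspec)
            xs.append(mutation_load(y, rspec))
            cfg = dc_replace(scan_config, seed=rep_seed)
            regions = call_repeats(seq, cfg)
            ys.append(unit_detection_fraction(regions, truth))
        rows.append({"x": float(np.mean(xs)), "y": float(np.mean(ys)),
                     "y_sd": float(np.std(ys, ddof=1)) if replicates > 1 else 0.0,
                     "replicates": replicates})
    return pd.DataFrame(rows)
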