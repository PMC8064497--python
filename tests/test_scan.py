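import numpy as np
import pytest

from rpwmtr.align import AlignmentResult
from rpwmtr.ga import GAConfig, GAResult
from rpwmtr.pwm import WeightMatrix, generate_matrix
from rpwmtr.scan import (ScanConfig, ScanResult, TRRegion, _local_maxima_1d,
                         call_repeats, cell_seed, find_local_maxima,
                         scan_sequence)
from rpwmtr.seqio import EncodedSequence, encode_sequence

from conftest import make_tandem


def tiny_config(**kw):
    """A desk-scale scan configuration for short fixtures."""
    defaults = dict(window_length=300, step=50, n_min=4, n_max=6,
                    neighborhood=64, f0=390.0,
                    ga=GAConfig(population=10, max_cycles=30, stall_limit=30),
                    seed=5)
    defaults.update(kw)
    return ScanConfig(**defaults)


def synthetic_scan_result(surface, config, seq_len=2000):
    """Wrap a hand-written surface in a ScanResult with stub GA caches."""
    n_vals = np.arange(config.n_min, config.n_max + 1)
    k_grid = np.arange(0, seq_len - config.window_length + 1, config.step)
    assert surface.shape == (n_vals.size, k_grid.size)
    rng = np.random.default_rng(0)
    seq = EncodedSequence("syn", rng.integers(1, 5, seq_len))
    cache = {}
    for ni, n in enumerate(n_vals):
        W = generate_matrix(int(n), seed=int(n))
        for ki, k in enumerate(k_grid):
            if surface[ni, ki] > 0:
                cache[(int(k), int(n))] = GAResult(
                    best_matrix=W, best_score=float(surface[ni, ki]),
                    cycles_run=1, converged=True)
    return ScanResult(seq=seq, config=config, k_grid=k_grid, n_values=n_vals,
                      surface=surface, window_passed=np.ones(k_grid.size, bool),
                      cache=cache)


class TestScanSequence:
    def test_sequence_shorter_than_window_rejected(self, rng):
        seq = EncodedSequence("s", rng.integers(1, 5, 200))
        with pytest.raises(ValueError, match="window"):
            scan_sequence(seq, tiny_config(window_length=300))

    def test_single_window_boundary(self, rng):
        seq = EncodedSequence("s", rng.integers(1, 5, 300))
        res = scan_sequence(seq, tiny_config())
        assert res.k_grid.tolist() == [0]
        assert res.surface.shape == (3, 1)

    def test_triplet_periodic_windows_skipped(self):
        seq = encode_sequence("atc" * 150)
        res = scan_sequence(seq, tiny_config())
        assert not res.window_passed.any()
        assert np.all(res.surface == 0.0)
        assert res.cache == {}

    def test_surface_nonnegative(self, rng):
        seq = EncodedSequence("s", rng.integers(1, 5, 450))
        res = scan_sequence(seq, tiny_config())
        assert np.all(res.surface >= 0.0)

    def test_cell_seed_depends_on_all_inputs(self):
        base = cell_seed(1, "chr1", 100, 6)
        assert cell_seed(1, "chr1", 100, 6) == base
        assert cell_seed(2, "chr1", 100, 6) != base
        assert cell_seed(1, "chr2", 100, 6) != base
        assert cell_seed(1, "chr1", 110, 6) != base
        assert cell_seed(1, "chr1", 100, 7) != base


class TestLocalMaxima:
    def test_single_cell_above_threshold(self):
        cfg = tiny_config()
        surface = np.zeros((3, 35))
        surface[1, 10] = 400.0
        regions = find_local_maxima(synthetic_scan_result(surface, cfg))
        assert len(regions) == 1
        assert regions[0].n == 5
        assert regions[0].mfmax == 400.0

    def test_weaker_neighbor_same_period_suppressed(self):
        cfg = tiny_config()
        surface = np.zeros((3, 35))
        surface[1, 10] = 500.0
        surface[1, 20] = 450.0  # 10 grid steps away, within ±64
        regions = find_local_maxima(synthetic_scan_result(surface, cfg))
        assert [r.mfmax for r in regions] == [500.0]

    def test_weaker_cell_at_other_period_suppressed(self):
        cfg = tiny_config()
        surface = np.zeros((3, 35))
        surface[0, 10] = 500.0
        surface[2, 14] = 450.0  # other period, same neighborhood
        regions = find_local_maxima(synthetic_scan_result(surface, cfg))
        assert len(regions) == 1
        assert regions[0].n == 4

    def test_threshold_is_strict(self):
        cfg = tiny_config(f0=390.0)
        surface = np.zeros((3, 35))
        surface[0, 5] = 389.9
        assert find_local_maxima(synthetic_scan_result(surface, cfg)) == []
        surface[0, 5] = 390.0  # equal is still not ">"
        assert find_local_maxima(synthetic_scan_result(surface, cfg)) == []

    def test_distant_maxima_both_survive(self):
        cfg = tiny_config(neighborhood=5)
        surface = np.zeros((3, 35))
        surface[1, 2] = 450.0
        surface[1, 20] = 440.0  # 18 grid steps apart > neighborhood 5
        regions = find_local_maxima(synthetic_scan_result(surface, cfg))
        assert sorted(r.mfmax for r in regions) == [440.0, 450.0]

    def test_1d_helper_strictness(self):
        row = np.array([0.0, 5.0, 5.0, 0.0, 7.0])
        # the tied 5s kill each other; 7 wins its neighborhood
        assert _local_maxima_1d(row, radius=2).tolist() == [4]


class TestCallRepeats:
    def test_planted_array_recovered_with_exact_period(self, rng):
        unit = np.array([1, 3, 2, 2, 4])  # period 5: no triplet-phase lock
        seq = make_tandem(unit, 80, flank=50, rng=rng, id="p5")
        cfg = tiny_config(window_length=300, step=100, n_min=4, n_max=6,
                          f0=390.0,
                          ga=GAConfig(population=12, max_cycles=40, stall_limit=40))
        regions = call_repeats(seq, cfg)
        assert len(regions) == 1
        r = regions[0]
        assert r.n == 5
        assert r.mfmax > 390.0
        # span lies inside the planted array (50 .. 450) and inside its window
        assert 0 <= r.window_start <= r.start
        assert r.end <= r.window_start + cfg.window_length
        assert len(r) >= r.n

    def test_random_sequence_yields_no_regions(self, rng):
        seq = EncodedSequence("null", rng.integers(1, 5, 800))
        regions = call_repeats(seq, tiny_config(step=100))
        assert regions == []

    def test_deterministic_given_seed(self, rng):
        unit = np.array([1, 3, 2, 2, 4])
        seq = make_tandem(unit, 80, flank=30, rng=rng)
        cfg = tiny_config(window_length=300, step=150, n_min=5, n_max=5,
                          ga=GAConfig(population=8, max_cycles=20, stall_limit=20))
        a = call_repeats(seq, cfg)
        b = call_repeats(seq, cfg)
        assert [(r.start, r.end, r.n, r.mfmax) for r in a] == \
               [(r.start, r.end, r.n, r.mfmax) for r in b]

    def test_no_two_regions_share_period_within_neighborhood(self, rng):
        cfg = tiny_config()
        surface = np.zeros((3, 35))
        surface[1, 3] = 420.0
        surface[1, 30] = 410.0  # 27 steps apart, within default ±64
        regions = find_local_maxima(synthetic_scan_result(surface, cfg))
        same_n = [r for r in regions if r.n == 5]
        assert len(same_n) <= 1
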