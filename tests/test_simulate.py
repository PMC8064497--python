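import numpy as np
import pytest

from rpwmtr.scan import TRRegion
from rpwmtr.simulate import (MutationVector, PlantedRepeatSpec, TruthSet,
                             central_window, mutation_load,
                             plant_tandem_repeats, six_nt_spec, subs_for_load,
                             thirty_nt_spec, unit_detection_fraction)


def load_oracle(y: np.ndarray, unit_length: int, copies: int) -> float:
    """Literal ordered-pair double sum for the divergence measure x."""
    u = y.reshape(copies, unit_length).sum(axis=1)
    total = 0.0
    pairs = 0
    for i in range(copies):
        for j in range(copies):
            if i != j:
                total += u[i] + u[j]
                pairs += 1
    return total / (unit_length * pairs)


class TestPlanting:
    def test_unmutated_array_is_exact_tandem(self):
        spec = PlantedRepeatSpec(unit_length=7, copies=40, seed=3)
        seq, y, truth = plant_tandem_repeats(spec)
        codes = seq.codes
        assert len(seq) == 280
        assert np.array_equal(codes[:7], codes[7:14])
        assert mutation_load(y, spec) == 0.0
        assert len(truth.spans) == 40
        assert truth.spans[0] == (0, 7)

    def test_thirty_nt_benchmark_geometry(self):
        spec = thirty_nt_spec(0, seed=1)
        seq, y, truth = plant_tandem_repeats(spec)
        # 3000-nt core + 50 insertions - 50 deletions, no flanks
        assert len(seq) == 3000
        assert y.y.size == 3000

    def test_six_nt_benchmark_geometry(self):
        spec = six_nt_spec(0, seed=1)
        seq, y, truth = plant_tandem_repeats(spec)
        assert len(seq) == 1200  # 600-nt core +5 -5 indels + 2x300 flanks
        assert all(300 <= a < b <= 900 for a, b in truth.spans)

    def test_length_bookkeeping(self):
        spec = PlantedRepeatSpec(unit_length=10, copies=30, n_insertions=7,
                                 n_deletions=4, flank_length=20, seed=9)
        seq, _, _ = plant_tandem_repeats(spec)
        assert len(seq) == 300 + 7 - 4 + 40

    def test_substitution_draws_all_counted(self):
        spec = PlantedRepeatSpec(unit_length=6, copies=50, n_substitutions=123,
                                 seed=4)
        _, y, _ = plant_tandem_repeats(spec)
        assert y.y.sum() == 123

    def test_truth_spans_ordered_nonoverlapping(self):
        spec = thirty_nt_spec(2000, seed=7)
        _, _, truth = plant_tandem_repeats(spec)
        spans = truth.spans
        assert all(a < b for a, b in spans)
        assert all(b1 <= a2 for (_, b1), (a2, _) in zip(spans, spans[1:]))

    def test_span_lengths_bounded_by_indels(self):
        spec = PlantedRepeatSpec(unit_length=12, copies=25, n_insertions=10,
                                 n_deletions=10, seed=2)
        _, _, truth = plant_tandem_repeats(spec)
        for a, b in truth.spans:
            assert 12 - 10 <= b - a <= 12 + 10

    def test_excess_deletions_rejected(self):
        with pytest.raises(ValueError, match="delete"):
            plant_tandem_repeats(PlantedRepeatSpec(unit_length=2, copies=3,
                                                   n_deletions=6))

    def test_deterministic(self):
        a, ya, _ = plant_tandem_repeats(six_nt_spec(500, seed=11))
        b, yb, _ = plant_tandem_repeats(six_nt_spec(500, seed=11))
        assert np.array_equal(a.codes, b.codes)
        assert np.array_equal(ya.y, yb.y)


class TestMutationLoad:
    def test_zero_for_no_substitutions(self):
        spec = PlantedRepeatSpec(unit_length=5, copies=10)
        assert mutation_load(MutationVector(np.zeros(50)), spec) == 0.0

    def test_uniform_single_hits_give_two(self):
        # one draw at every position: every ordered pair contributes
        # 2 * unit_length, normalised by unit_length -> x = 2
        spec = PlantedRepeatSpec(unit_length=30, copies=100)
        y = MutationVector(np.ones(3000))
        assert mutation_load(y, spec) == pytest.approx(2.0)

    def test_matches_literal_double_sum(self, rng):
        spec = PlantedRepeatSpec(unit_length=6, copies=20)
        y = rng.integers(0, 4, 120)
        assert mutation_load(MutationVector(y), spec) == pytest.approx(
            load_oracle(y, 6, 20))

    def test_linear_in_counts(self, rng):
        spec = PlantedRepeatSpec(unit_length=5, copies=12)
        y = rng.integers(0, 3, 60)
        x1 = mutation_load(MutationVector(y), spec)
        x2 = mutation_load(MutationVector(2 * y), spec)
        assert x2 == pytest.approx(2 * x1)

    def test_invariant_under_unit_permutation(self, rng):
        spec = PlantedRepeatSpec(unit_length=4, copies=15)
        y = rng.integers(0, 5, 60).reshape(15, 4)
        x1 = mutation_load(MutationVector(y.ravel()), spec)
        perm = rng.permutation(15)
        x2 = mutation_load(MutationVector(y[perm].ravel()), spec)
        assert x2 == pytest.approx(x1)

    def test_subs_for_load_inverts(self):
        spec = thirty_nt_spec(0)
        assert subs_for_load(3.2, spec) == 4800
        assert subs_for_load(2.0, spec) == 3000
        assert subs_for_load(3.0, six_nt_spec(0)) == 900

    def test_expected_load_at_full_density(self):
        # 3000 draws on the 3000-nt core: x = 2 in expectation
        spec = thirty_nt_spec(3000, seed=5)
        _, y, _ = plant_tandem_repeats(spec)
        assert mutation_load(y, spec) == pytest.approx(2.0, abs=1e-9)


class TestDetectionScoring:
    def _region(self, start, end, n=6):
        return TRRegion(seq_id="s", start=start, end=end, n=n, mfmax=500.0,
                        matrix=None, alignment=None, window_start=0)

    def test_full_coverage(self):
        truth = TruthSet(spans=[(0, 6), (6, 12)], period=6)
        regs = [self._region(0, 12)]
        assert unit_detection_fraction(regs, truth) == 1.0

    def test_wrong_period_counts_zero(self):
        truth = TruthSet(spans=[(0, 6), (6, 12)], period=6)
        regs = [self._region(0, 12, n=12)]
        assert unit_detection_fraction(regs, truth) == 0.0

    def test_half_covered_unit_counts(self):
        truth = TruthSet(spans=[(0, 6)], period=6)
        assert unit_detection_fraction([self._region(0, 3)], truth) == 1.0
        assert unit_detection_fraction([self._region(0, 2)], truth) == 0.0


class TestCentralWindow:
    def test_short_sequence_unchanged(self, rng):
        from rpwmtr.seqio import EncodedSequence
        seq = EncodedSequence("s", rng.integers(1, 5, 100))
        assert central_window(seq, 650) is seq

    def test_long_sequence_centred(self):
        seq, _, _ = plant_tandem_repeats(thirty_nt_spec(0, seed=1))
        win = central_window(seq, 650)
        assert len(win) == 650
        assert win.offset == (3000 - 650) // 2
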