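"""Immediate variety and acoustic contrast statistics."""

import math

import numpy as np
import pytest

import vocalseq as vs
from vocalseq.organization import (
    acoustic_contrast,
    contrast_permutation_test,
    count_immediate_repeats,
    repetition_permutation_test,
)
from vocalseq.types import UnitClass

from conftest import mk_acoustics, mk_seq

V = UnitClass.MIMETIC_VOCAL
NV = UnitClass.MIMETIC_NONVOCAL


class TestRepeatCount:
    def test_single_adjacent_repeat(self):
        seq = mk_seq("b", "p", ["d", "A", "A", "B"])
        assert count_immediate_repeats([seq]) == 1

    def test_nonvocal_breaks_adjacency(self):
        seq = mk_seq("b", "p", ["A", "x", "A"], classes=[V, NV, V])
        assert count_immediate_repeats([seq]) == 0

    def test_nonvocal_skipped_in_alternate_mode(self):
        seq = mk_seq("b", "p", ["A", "x", "A"], classes=[V, NV, V])
        assert count_immediate_repeats([seq], skip_nonvocal_for_adjacency=True) == 1

    def test_nonvocal_repeats_not_counted(self):
        seq = mk_seq("b", "p", ["x", "x"], classes=[NV, NV])
        assert count_immediate_repeats([seq]) == 0
        assert count_immediate_repeats([seq], vocal_only=False) == 1

    def test_never_counts_across_sequences(self):
        seqs = [mk_seq("b", "p", ["A", "B"]), mk_seq("b", "p", ["B", "C"])]
        assert count_immediate_repeats(seqs) == 0

    def test_invariant_under_recoding(self, rng):
        codes = [str(t) for t in rng.integers(0, 4, 30)]
        seq = mk_seq("b", "p", codes)
        mapping = {"0": "w", "1": "x", "2": "y", "3": "z"}
        recoded = mk_seq("b", "p", [mapping[c] for c in codes])
        assert count_immediate_repeats([seq]) == count_immediate_repeats([recoded])

    def test_study_scale_planted_repeats(self):
        # 6593 units with exactly 16 planted adjacent repeats
        seqs = []
        n_units = 0
        k = 0
        while n_units < 6593 - 15 * 16:
            codes = [f"c{(k + i) % 40}" for i in range(14)]  # all distinct
            seqs.append(mk_seq("b", "p", codes))
            n_units += 14
            k += 1
        # pad to exactly 6593 - 16 then plant 16 repeats by duplication
        pad = 6593 - 16 - n_units
        if pad >= 2:
            seqs.append(mk_seq("b", "p", [f"q{i}" for i in range(pad)]))
            n_units += pad
        planted = 0
        for seq_idx in range(16):
            s = seqs[seq_idx]
            codes = list(s.codes)
            codes.insert(3, codes[3])  # duplicate one interior unit
            seqs[seq_idx] = mk_seq(s.bird_id, s.population_id, codes)
            planted += 1
            n_units += 1
        assert n_units == 6593
        assert sum(len(s) for s in seqs) == 6593
        assert count_immediate_repeats(seqs) == 16


class TestRepetitionPermutation:
    def test_all_distinct_codes_degenerate(self):
        seqs = [mk_seq("b", "p", ["A", "B", "C"]), mk_seq("b", "p", ["D", "E"])]
        res = repetition_permutation_test(seqs, n_perm=20, seed=0)
        assert res.observed_count == 0
        assert res.perm_mean_count == 0
        assert math.isnan(res.z)

    def test_forced_repeat_pair_matches_null_exactly(self):
        # a two-unit sequence AA has exactly one repeat under any shuffle
        seqs = [mk_seq("b", "p", ["A", "A"]), mk_seq("b", "p", ["B", "C"])]
        res = repetition_permutation_test(seqs, n_perm=30, seed=1)
        assert res.observed_count == 1
        assert res.perm_mean_count == 1.0
        assert res.perm_sd == 0.0

    def test_null_mean_matches_combinatorial_expectation(self):
        # 10 units, one code duplicated: P(the two copies are adjacent in a
        # uniform permutation) = 2/10, so the expected repeat count is 0.2
        codes = ["a", "a"] + [f"u{i}" for i in range(8)]
        seqs = [mk_seq("b", "p", codes)]
        res = repetition_permutation_test(seqs, n_perm=4000, seed=3)
        assert res.perm_mean_count == pytest.approx(0.2, abs=0.025)

    def test_single_unit_data_rejected(self):
        with pytest.raises(ValueError):
            repetition_permutation_test([mk_seq("b", "p", ["A"])], n_perm=5)

    def test_rates_reported_as_percentages(self):
        seqs = [mk_seq("b", "p", ["A", "A", "B", "C"])]
        res = repetition_permutation_test(seqs, n_perm=10, seed=0)
        assert res.observed_rate_pct == pytest.approx(100.0 / 4)


def _acoustic_seq(bird, pop, values, var="peak_frequency"):
    """Sequence whose units differ only in one acoustic variable."""
    base = dict(peak=3.0, low=2.0, high=4.0, dur=0.5, ent=4.0, power=60.0)
    key = {"peak_frequency": "peak", "duration_90pct": "dur"}[var]
    acoustics = []
    for v in values:
        kw = dict(base)
        kw[key] = v
        acoustics.append(mk_acoustics(**kw))
    codes = [f"u{i}" for i in range(len(values))]
    return mk_seq(bird, pop, codes, acoustics=tuple(acoustics))


class TestAcousticContrast:
    def test_hand_computed_mean_difference(self):
        seq = _acoustic_seq("b", "p", [1.0, 3.0, 2.0])
        res = acoustic_contrast([seq], group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        assert peak.observed_mean == pytest.approx(1.5)  # (|3-1| + |2-3|)/2

    def test_constant_values_zero_contrast(self):
        seq = _acoustic_seq("b", "p", [2.0, 2.0, 2.0])
        res = acoustic_contrast([seq], group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        assert peak.observed_mean == 0.0

    def test_two_stage_averaging(self):
        s1 = _acoustic_seq("b", "p", [1.0, 2.0])        # mean |diff| = 1
        s2 = _acoustic_seq("b", "p", [1.0, 4.0, 1.0])   # mean |diff| = 3
        res = acoustic_contrast([s1, s2], group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        assert peak.observed_mean == pytest.approx(2.0)  # (1 + 3) / 2
        pooled = acoustic_contrast([s1, s2], group_by=None, pooled_pairs=True)
        peak_p = next(r for r in pooled if r.variable == "peak_frequency")
        assert peak_p.observed_mean == pytest.approx((1 + 3 + 3) / 3)

    def test_missing_units_skipped_per_variable(self):
        seq = _acoustic_seq("b", "p", [1.0, 5.0, 2.0])
        acoustics = list(seq.acoustics)
        acoustics[1] = None  # middle unit unmeasured
        seq2 = mk_seq("b", "p", seq.codes, acoustics=tuple(acoustics))
        res = acoustic_contrast([seq2], group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        # no consecutive measured pairs remain
        assert math.isnan(peak.observed_mean) and peak.n_sequences == 0

    def test_structural_shape_per_population_and_overall(self, small_dataset):
        seqs, _ = vs.segment_dataset(small_dataset.bouts_by_bird)
        res = acoustic_contrast(seqs, group_by="population")
        groups = {r.group for r in res}
        assert groups == {"all", "P1", "P2", "P3"}
        for g in groups:
            assert len([r for r in res if r.group == g]) == 7


class TestContrastPermutation:
    def test_length_two_sequences_degenerate(self):
        # |a - b| is symmetric, so two-unit sequences are shuffle-invariant
        seqs = [
            _acoustic_seq("b", "p", [1.0, 4.0]),
            _acoustic_seq("b", "p", [2.0, 5.0]),
        ]
        res = contrast_permutation_test(seqs, n_perm=20, seed=0, group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        assert peak.observed_mean == pytest.approx(peak.perm_mean)
        assert math.isnan(peak.z)

    def test_alternating_extremes_beat_null(self):
        # low/high alternation maximizes consecutive contrast; shuffles can
        # only reduce it
        seqs = [
            _acoustic_seq("b", "p", [1.0, 5.0, 1.0, 5.0, 1.0, 5.0, 1.0, 3.0])
            for _ in range(12)
        ]
        res = contrast_permutation_test(seqs, n_perm=60, seed=2, group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        assert peak.observed_mean > peak.perm_mean
        assert peak.z > 3

    def test_targeted_variable_only(self):
        # frequency alternates, duration constant across unit types:
        # z must be positive for frequency and near zero for duration
        rng = np.random.default_rng(9)
        seqs = []
        for _ in range(15):
            freqs = [1.0 if i % 2 == 0 else 5.0 for i in range(10)]
            acoustics = tuple(
                mk_acoustics(peak=f + rng.normal(0, 0.05), dur=0.5 + rng.normal(0, 0.01))
                for f in freqs
            )
            seqs.append(
                mk_seq("b", "p", [f"u{i}" for i in range(10)], acoustics=acoustics)
            )
        res = contrast_permutation_test(seqs, n_perm=80, seed=4, group_by=None)
        peak = next(r for r in res if r.variable == "peak_frequency")
        dur = next(r for r in res if r.variable == "duration_90pct")
        assert peak.z > 3
        assert abs(dur.z) < 3
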