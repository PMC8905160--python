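"""Levenshtein distance, LSI, pairwise matrices and the shuffle null."""

import functools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vocalseq as vs
from vocalseq.similarity import (
    _pairwise_lsi_kernel,
    encode_sequences,
    group_means,
    pairwise_lsi,
    permutation_null_lsi,
)

from conftest import mk_seq


def lev_oracle(a, b):
    """Memoized recursive definition of the edit distance."""
    a, b = tuple(a), tuple(b)

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


tokens = st.lists(st.sampled_from(["a", "b", "c", "dd", "e1"]), max_size=12)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (["d", "A", "B"], ["d", "A", "B"], 0),
            (list("kitten"), list("sitting"), 3),
            (["d"], [], 1),
            ([], [], 0),
            (["x", "y"], ["y", "x"], 2),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert vs.levenshtein(a, b) == expected

    def test_matches_recursive_oracle_on_random_pairs(self, rng):
        # the spec of the DP is the naive recursion; compare on 1000 pairs
        alphabet = [f"t{i}" for i in range(8)]
        for _ in range(1000):
            la, lb = rng.integers(0, 11, size=2)
            a = list(rng.choice(alphabet, size=la))
            b = list(rng.choice(alphabet, size=lb))
            assert vs.levenshtein(a, b) == lev_oracle(a, b)

    @given(tokens, tokens, tokens)
    def test_triangle_inequality(self, a, b, c):
        assert vs.levenshtein(a, c) <= vs.levenshtein(a, b) + vs.levenshtein(b, c)

    @given(tokens, tokens)
    def test_symmetry_and_identity(self, a, b):
        assert vs.levenshtein(a, b) == vs.levenshtein(b, a)
        assert vs.levenshtein(a, a) == 0

    def test_tokens_not_characters(self):
        # multi-character codes are single tokens: one substitution, not many
        assert vs.levenshtein(["ab"], ["cd"]) == 1
        assert vs.levenshtein(["ab", "cd"], ["abcd"]) == 2

    def test_kernel_agrees_with_reference(self, rng):
        seqs = [
            mk_seq("b", "p", [str(t) for t in rng.integers(0, 6, rng.integers(1, 15))])
            for _ in range(30)
        ]
        codes, lengths, _ = encode_sequences(seqs)
        cond = _pairwise_lsi_kernel(codes, lengths)
        k = 0
        for i in range(30):
            for j in range(i + 1, 30):
                expected = vs.lsi(seqs[i].codes, seqs[j].codes)
                assert cond[k] == pytest.approx(expected, abs=1e-12)
                k += 1

    def test_edlib_cross_check(self, rng):
        # independent C implementation of the same distance
        edlib = pytest.importorskip("edlib")
        for _ in range(200):
            a = "".join(rng.choice(list("abcdef"), size=rng.integers(0, 20)))
            b = "".join(rng.choice(list("abcdef"), size=rng.integers(1, 20)))
            expected = edlib.align(a, b)["editDistance"]
            assert vs.levenshtein(list(a), list(b)) == expected


class TestLsi:
    def test_identical_sequences(self):
        assert vs.lsi(list("abcde"), list("abcde")) == 1.0

    def test_single_substitution(self):
        assert vs.lsi(["a", "b", "c"], ["a", "b", "d"]) == pytest.approx(2 / 3)

    def test_disjoint_codes_zero(self):
        assert vs.lsi(["a", "b", "c", "d"], ["x", "y"]) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            vs.lsi([], [])

    @given(tokens.filter(bool), tokens.filter(bool))
    def test_bounded_and_symmetric(self, a, b):
        v = vs.lsi(a, b)
        assert 0.0 <= v <= 1.0
        assert v == vs.lsi(b, a)

    def test_invariant_under_recoding(self, rng):
        # bijective relabelling of codes leaves every LSI unchanged
        seqs = [list(rng.choice(list("abcde"), size=10)) for _ in range(10)]
        mapping = dict(zip("abcde", "VWXYZ"))
        for i in range(10):
            for j in range(i):
                a, b = seqs[i], seqs[j]
                ra = [mapping[c] for c in a]
                rb = [mapping[c] for c in b]
                assert vs.lsi(a, b) == vs.lsi(ra, rb)


class TestPairwise:
    def test_pair_count_formula(self, small_sequences):
        m = pairwise_lsi(small_sequences)
        n = len(small_sequences)
        assert m.n_pairs == n * (n - 1) // 2

    def test_identical_pair_gives_one(self):
        seqs = [mk_seq("b1", "p", "dAB"), mk_seq("b2", "p", "dAB")]
        m = pairwise_lsi(seqs)
        assert m.values[0, 1] == 1.0

    def test_matches_pair_by_pair_loop(self, rng):
        seqs = [
            mk_seq("b", "p", [str(t) for t in rng.integers(0, 5, rng.integers(2, 10))])
            for _ in range(10)
        ]
        m = pairwise_lsi(seqs)
        assert np.allclose(m.values, m.values.T)
        for i in range(10):
            for j in range(10):
                if i != j:
                    assert m.values[i, j] == pytest.approx(
                        vs.lsi(seqs[i].codes, seqs[j].codes)
                    )


class TestGroupMeans:
    def test_pair_counting_two_birds_one_population(self):
        seqs = [
            mk_seq("b1", "p", "dA"), mk_seq("b1", "p", "dB"),
            mk_seq("b2", "p", "dC"), mk_seq("b2", "p", "dE"),
        ]
        gm = group_means(pairwise_lsi(seqs))
        assert gm.n_pairs["within_individual"] == 2
        assert gm.n_pairs["between_individual_same_population"] == 4
        assert gm.n_pairs["between_populations"] == 0
        assert math.isnan(gm.mean["between_populations"])

    def test_all_identical_sequences_mean_one(self):
        pop_of = {"b0": "p0", "b1": "p0", "b2": "p1"}
        seqs = [mk_seq(f"b{i % 3}", pop_of[f"b{i % 3}"], "dABC") for i in range(6)]
        gm = group_means(pairwise_lsi(seqs))
        for g, v in gm.mean.items():
            if gm.n_pairs[g]:
                assert v == 1.0

    def test_bird_in_two_populations_rejected(self):
        seqs = [mk_seq("b0", "p0", "dA"), mk_seq("b0", "p1", "dB")]
        with pytest.raises(ValueError, match="multiple populations"):
            group_means(pairwise_lsi(seqs))

    def test_group_counts_partition_all_pairs(self, small_sequences):
        m = pairwise_lsi(small_sequences)
        gm = group_means(m)
        assert sum(gm.n_pairs.values()) == m.n_pairs

    def test_sharing_decays_with_level(self, small_sequences):
        # generator is built so sharing decays from bird to population level
        gm = group_means(pairwise_lsi(small_sequences))
        assert (
            gm.mean["within_individual"]
            >= gm.mean["between_individual_same_population"]
            >= gm.mean["between_populations"]
        )

    def test_per_bird_weighting_mode_runs(self, small_sequences):
        gm = group_means(pairwise_lsi(small_sequences), weighting="per_bird")
        assert all(0 <= gm.mean[g] <= 1 for g in gm.mean)


class TestPermutationNull:
    def test_structured_data_beats_null(self, small_sequences):
        res = permutation_null_lsi(small_sequences, n_perm=30, seed=1)
        r = res["within_individual"]
        assert r.observed > r.perm_mean
        assert r.z > 3

    def test_reproducible_under_seed(self, small_sequences):
        a = permutation_null_lsi(small_sequences[:20], n_perm=10, seed=42)
        b = permutation_null_lsi(small_sequences[:20], n_perm=10, seed=42)
        for g in a:
            if math.isnan(a[g].perm_mean):  # group empty in this subset
                assert math.isnan(b[g].perm_mean)
            else:
                assert a[g].perm_mean == b[g].perm_mean

    def test_shuffle_invariant_sequences_degenerate(self):
        # repeats of one code: every permutation equals the original
        seqs = [
            mk_seq("b1", "p", ["A"] * 4),
            mk_seq("b1", "p", ["A"] * 4),
            mk_seq("b2", "p", ["B"] * 3),
        ]
        res = permutation_null_lsi(seqs, n_perm=20, seed=0)
        r = res["within_individual"]
        assert r.perm_sd == 0.0
        assert math.isnan(r.z) and "degenerate" in r.note

    def test_length_one_sequences_flagged(self):
        seqs = [mk_seq("b1", "p", ["A"]), mk_seq("b1", "p", ["B"]),
                mk_seq("b2", "p", ["C"])]
        res = permutation_null_lsi(seqs, n_perm=10, seed=0)
        r = res["within_individual"]
        assert r.observed == r.perm_mean
        assert math.isnan(r.z)

    def test_null_bounded(self, small_sequences):
        res = permutation_null_lsi(small_sequences[:25], n_perm=15, seed=3)
        for r in res.values():
            if not math.isnan(r.perm_mean):
                assert 0.0 <= r.perm_mean <= 1.0
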