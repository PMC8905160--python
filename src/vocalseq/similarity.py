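"""Edit-distance sequence similarity and its permutation null.

Two sequences of unit codes are compared with the Levenshtein distance
(LD), the minimum number of single-token insertions, deletions and
substitutions turning one into the other. Because sequences differ in
length, LD is standardized to a Levenshtein similarity index

    LSI = 1 - LD / max(len(a), len(b))

ranging from 0 (maximally different) to 1 (identical). The observed mean
LSI within individuals, between individuals of the same population, and
between populations is compared against a null in which unit order is
shuffled uniformly within every sequence (composition preserved): a high
observed mean relative to the null shows sequences are more repeatable
than their repertoire overlap alone predicts.

Distances are computed on token lists, never on concatenated characters,
so multi-character unit codes are not split. A numba-compiled kernel
drives the all-pairs matrix; :func:`levenshtein` is the plain reference
implementation of the same dynamic programme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .types import MimeticSequence

GROUPS = (
    "within_individual",
    "between_individual_same_population",
    "between_populations",
)


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Unit-cost edit distance between two token sequences.

    Classic two-row dynamic programme; satisfies the metric axioms
    (non-negativity, identity, symmetry, triangle inequality).
    """
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (ca != cb),  # substitution
            )
        prev = cur
    return prev[-1]


def lsi(a: Sequence[str], b: Sequence[str]) -> float:
    """Levenshtein similarity index: ``1 - LD / max(len(a), len(b))``."""
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("LSI is undefined for two empty sequences")
    return 1.0 - levenshtein(a, b) / m


@njit(cache=False)
def _lev_kernel(codes: np.ndarray, la: int, ia: int, lb: int, ib: int, work: np.ndarray) -> int:
    # codes: (n_seq, max_len) int32; rows ia, ib hold the two sequences
    if la == 0:
        return lb
    if lb == 0:
        return la
    for j in range(lb + 1):
        work[j] = j
    for i in range(1, la + 1):
        prev_diag = work[0]
        work[0] = i
        ca = codes[ia, i - 1]
        for j in range(1, lb + 1):
            tmp = work[j]
            cost = 0 if ca == codes[ib, j - 1] else 1
            d = prev_diag + cost
            if work[j] + 1 < d:
                d = work[j] + 1
            if work[j - 1] + 1 < d:
                d = work[j - 1] + 1
            work[j] = d
            prev_diag = tmp
    return work[lb]


@njit(cache=False)
def _pairwise_lsi_kernel(codes: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    work = np.empty(codes.shape[1] + 1, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            la = lengths[i]
            lb = lengths[j]
            d = _lev_kernel(codes, la, i, lb, j, work)
            m = la if la > lb else lb
            out[k] = 1.0 - d / m
            k += 1
    return out


def encode_sequences(
    sequences: Sequence[MimeticSequence],
) -> Tuple[np.ndarray, np.ndarray, Dict[str, int]]:
    """Map sequences of string codes to a padded int32 matrix.

    Returns ``(codes, lengths, vocabulary)`` where ``codes[i, :lengths[i]]``
    are the integer tokens of sequence ``i`` (padding is -1).
    """
    vocab: Dict[str, int] = {}
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    if (lengths < 1).any():
        raise ValueError("all sequences must have length >= 1")
    mat = np.full((len(sequences), int(lengths.max())), -1, dtype=np.int32)
    for i, s in enumerate(sequences):
        for j, tok in enumerate(s.codes):
            mat[i, j] = vocab.setdefault(tok, len(vocab))
    return mat, lengths, vocab


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise LSI matrix with bird/population labels."""

    values: np.ndarray
    bird_ids: np.ndarray
    population_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("LSI values must lie in [0, 1]")
        self.values = v
        self.bird_ids = np.asarray(self.bird_ids, dtype=object)
        self.population_ids = np.asarray(self.population_ids, dtype=object)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of unordered off-diagonal pairs, n(n-1)/2."""
        return self.n * (self.n - 1) // 2

    def condensed(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    def dissimilarity(self) -> np.ndarray:
        """The 1 - LSI dissimilarity matrix (zero diagonal)."""
        return 1.0 - self.values


def _square_from_condensed(cond: np.ndarray, n: int) -> np.ndarray:
    m = np.ones((n, n), dtype=np.float64)
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = cond
    m[ju, iu] = cond
    return m


def pairwise_lsi(sequences: Sequence[MimeticSequence]) -> SimilarityMatrix:
    """All-pairs LSI over a sequence set (each unordered pair computed once)."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    codes, lengths, _ = encode_sequences(sequences)
    cond = _pairwise_lsi_kernel(codes, lengths)
    return SimilarityMatrix(
        values=_square_from_condensed(cond, len(sequences)),
        bird_ids=np.array([s.bird_id for s in sequences], dtype=object),
        population_ids=np.array([s.population_id for s in sequences], dtype=object),
    )


def _pair_group_masks(
    bird_ids: np.ndarray, population_ids: np.ndarray
) -> Dict[str, np.ndarray]:
    seen: Dict[object, object] = {}
    for b, p in zip(bird_ids, population_ids):
        if seen.setdefault(b, p) != p:
            raise ValueError(
                f"bird {b!r} appears in multiple populations "
                f"({seen[b]!r} and {p!r}); birds must nest within populations"
            )
    n = len(bird_ids)
    iu, ju = np.triu_indices(n, k=1)
    same_bird = bird_ids[iu] == bird_ids[ju]
    same_pop = population_ids[iu] == population_ids[ju]
    return {
        "within_individual": same_bird,
        "between_individual_same_population": (~same_bird) & same_pop,
        "between_populations": ~same_pop,
    }


@dataclass
class GroupMeans:
    """Mean +/- sd of pairwise LSI per comparison group."""

    mean: Dict[str, float]
    sd: Dict[str, float]
    n_pairs: Dict[str, int]

    def as_rows(self) -> list[dict]:
        return [
            {
                "group": g,
                "mean_lsi": self.mean[g],
                "sd_lsi": self.sd[g],
                "n_pairs": self.n_pairs[g],
            }
            for g in GROUPS
        ]


def group_means(
    matrix: SimilarityMatrix, *, weighting: str = "pooled"
) -> GroupMeans:
    """Mean LSI within individuals, within and between populations.

    Every unordered off-diagonal pair belongs to exactly one group. With
    ``weighting="pooled"`` (default) means and sds are over pair values;
    ``weighting="per_bird"`` first averages each bird's (or bird-pair's)
    pairs, then averages those.
    """
    masks = _pair_group_masks(matrix.bird_ids, matrix.population_ids)
    cond = matrix.condensed()
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    n_pairs: Dict[str, int] = {}
    n = matrix.n
    iu, ju = np.triu_indices(n, k=1)
    for g in GROUPS:
        mask = masks[g]
        n_pairs[g] = int(mask.sum())
        if n_pairs[g] == 0:
            mean[g] = math.nan
            sd[g] = math.nan
            continue
        vals = cond[mask]
        if weighting == "pooled":
            mean[g] = float(vals.mean())
            sd[g] = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
        elif weighting == "per_bird":
            keys = [
                tuple(sorted((matrix.bird_ids[a], matrix.bird_ids[b])))
                for a, b in zip(iu[mask], ju[mask])
            ]
            sums: Dict[tuple, list] = {}
            for key, v in zip(keys, vals):
                sums.setdefault(key, []).append(v)
            per = np.array([np.mean(v) for v in sums.values()])
            mean[g] = float(per.mean())
            sd[g] = float(per.std(ddof=1)) if len(per) > 1 else math.nan
        else:
            raise ValueError("weighting must be 'pooled' or 'per_bird'")
    assert sum(n_pairs.values()) == matrix.n_pairs
    return GroupMeans(mean=mean, sd=sd, n_pairs=n_pairs)


@dataclass
class PermutationResult:
    """Observed statistic against a permutation-null distribution.

    ``z`` is the standard score (observed - null mean) / null sd and ``p``
    the two-sided normal tail probability; both are NaN (with a note) when
    the null is degenerate (sd = 0).
    """

    observed: float
    perm_mean: float
    perm_sd: float
    n_permutations: int
    z: float
    p: float
    note: str = ""


def _z_test(observed: float, null_values: np.ndarray) -> PermutationResult:
    mu = float(null_values.mean())
    sdv = float(null_values.std(ddof=1)) if len(null_values) > 1 else 0.0
    if sdv > 0:
        z = (observed - mu) / sdv
        p = math.erfc(abs(z) / math.sqrt(2.0))
        note = ""
    else:
        z = math.nan
        p = math.nan
        note = "degenerate null (sd = 0); z undefined"
    return PermutationResult(
        observed=observed,
        perm_mean=mu,
        perm_sd=sdv,
        n_permutations=len(null_values),
        z=z,
        p=p,
        note=note,
    )


def shuffle_within_rows(
    codes: np.ndarray, lengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly shuffle each row's first ``lengths[i]`` tokens (in place copy)."""
    out = codes.copy()
    for i in range(out.shape[0]):
        L = int(lengths[i])
        if L > 1:
            perm = rng.permutation(L)
            out[i, :L] = codes[i, :L][perm]
    return out


def permutation_null_lsi(
    sequences: Sequence[MimeticSequence],
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> Dict[str, PermutationResult]:
    """Observed group-mean LSIs vs. the within-sequence order-shuffle null.

    Each permutation independently randomizes the unit order inside every
    sequence (all positions, composition preserved), recomputes the full
    pairwise LSI matrix and the three group means. Per-permutation RNG
    substreams are derived deterministically from ``seed`` so results do
    not depend on execution order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    matrix = pairwise_lsi(sequences)
    observed = group_means(matrix)
    codes, lengths, _ = encode_sequences(sequences)
    masks = _pair_group_masks(matrix.bird_ids, matrix.population_ids)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    null = {g: np.empty(n_perm) for g in GROUPS}
    for k in range(n_perm):
        rng = np.random.default_rng(children[k])
        shuffled = shuffle_within_rows(codes, lengths, rng)
        if k == 0:
            # composition must be preserved by the shuffle
            assert all(
                sorted(shuffled[i, : lengths[i]]) == sorted(codes[i, : lengths[i]])
                for i in range(min(len(sequences), 25))
            )
        cond = _pairwise_lsi_kernel(shuffled, lengths)
        for g in GROUPS:
            mask = masks[g]
            null[g][k] = cond[mask].mean() if mask.any() else math.nan
    results = {}
    for g in GROUPS:
        if math.isnan(observed.mean[g]):
            results[g] = PermutationResult(
                observed=math.nan,
                perm_mean=math.nan,
                perm_sd=math.nan,
                n_permutations=n_perm,
                z=math.nan,
                p=math.nan,
                note="no pairs in group",
            )
            continue
        results[g] = _z_test(observed.mean[g], null[g])
    return results
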