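"""Sequence-organization statistics: immediate variety and acoustic contrast.

Two properties of how units are ordered inside sequences are tested
against the same within-sequence order-shuffle null used for sequence
similarity:

* **Immediate variety** — how rarely a vocal unit is immediately repeated.
  The observed count of adjacent identical vocal units across all
  sequences is compared with counts from uniformly shuffled sequences;
  a strongly negative z means unit types are over-dispersed (singers
  avoid repeating themselves).

* **Acoustic contrast** — how different consecutive units sound. For each
  of the seven acoustic variables the mean absolute difference between
  consecutive units is computed within each sequence and then averaged
  across sequences (two-stage averaging); a positive z against the
  shuffle null means acoustically dissimilar units are juxtaposed more
  than repertoire composition alone predicts. Differences are unsigned:
  signed means would cancel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .similarity import PermutationResult, _z_test
from .types import ACOUSTIC_VARIABLES, MimeticSequence, UnitClass

logger = logging.getLogger(__name__)

ALL_GROUP = "all"


def count_immediate_repeats(
    sequences: Sequence[MimeticSequence],
    *,
    vocal_only: bool = True,
    skip_nonvocal_for_adjacency: bool = False,
) -> int:
    """Count adjacent identical units within sequences (never across them).

    With ``vocal_only`` (default) only repeats where both units are
    mimetic-vocal are counted; non-vocal units are given broad type codes
    that cannot be objectively matched, so repeats among them are ignored.
    By default a non-vocal unit *breaks* adjacency (strict positional
    adjacency); with ``skip_nonvocal_for_adjacency=True`` non-vocal units
    are skipped over when pairing neighbours.
    """
    total = 0
    for seq in sequences:
        if vocal_only and skip_nonvocal_for_adjacency:
            stream = [
                (c, k)
                for c, k in zip(seq.codes, seq.unit_classes)
                if k is UnitClass.MIMETIC_VOCAL
            ]
        else:
            stream = list(zip(seq.codes, seq.unit_classes))
        for (c1, k1), (c2, k2) in zip(stream, stream[1:]):
            if c1 != c2:
                continue
            if vocal_only and not (
                k1 is UnitClass.MIMETIC_VOCAL and k2 is UnitClass.MIMETIC_VOCAL
            ):
                continue
            total += 1
    return total


def total_units(sequences: Sequence[MimeticSequence]) -> int:
    return sum(len(s) for s in sequences)


@dataclass
class RepetitionResult:
    """Immediate-repetition test: observed vs. shuffled-order null."""

    observed_count: int
    observed_rate_pct: float
    perm_mean_count: float
    perm_mean_rate_pct: float
    perm_sd: float
    z: float
    p: float
    n_permutations: int
    n_units: int
    note: str = ""


def repetition_permutation_test(
    sequences: Sequence[MimeticSequence],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    *,
    vocal_only: bool = True,
    skip_nonvocal_for_adjacency: bool = False,
) -> RepetitionResult:
    """Compare the immediate-repeat count with its within-sequence shuffle null.

    Rates are also reported as percentages of the total unit count.
    """
    if not any(len(s) >= 2 for s in sequences):
        raise ValueError("need at least one sequence of length >= 2")
    observed = count_immediate_repeats(
        sequences,
        vocal_only=vocal_only,
        skip_nonvocal_for_adjacency=skip_nonvocal_for_adjacency,
    )
    n_units = total_units(sequences)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    null = np.empty(n_perm)
    for k in range(n_perm):
        rng = np.random.default_rng(children[k])
        shuffled = [_shuffle_sequence(s, rng) for s in sequences]
        null[k] = count_immediate_repeats(
            shuffled,
            vocal_only=vocal_only,
            skip_nonvocal_for_adjacency=skip_nonvocal_for_adjacency,
        )
    base = _z_test(float(observed), null)
    return RepetitionResult(
        observed_count=observed,
        observed_rate_pct=100.0 * observed / n_units,
        perm_mean_count=base.perm_mean,
        perm_mean_rate_pct=100.0 * base.perm_mean / n_units,
        perm_sd=base.perm_sd,
        z=base.z,
        p=base.p,
        n_permutations=n_perm,
        n_units=n_units,
        note=base.note,
    )


def _shuffle_sequence(seq: MimeticSequence, rng: np.random.Generator) -> MimeticSequence:
    """Uniformly shuffle unit order; classes and acoustics travel with units."""
    n = len(seq)
    if n < 2:
        return seq
    perm = rng.permutation(n)
    return MimeticSequence(
        bird_id=seq.bird_id,
        population_id=seq.population_id,
        codes=tuple(seq.codes[i] for i in perm),
        unit_classes=tuple(seq.unit_classes[i] for i in perm),
        acoustics=(
            tuple(seq.acoustics[i] for i in perm) if seq.acoustics is not None else None
        ),
        source_bout=seq.source_bout,
        position=seq.position,
    )


@dataclass
class ContrastResult:
    """Acoustic-contrast cell: one variable in one grouping."""

    variable: str
    group: str
    observed_mean: float
    observed_sd: float
    n_sequences: int
    perm_mean: float = math.nan
    perm_sd: float = math.nan
    z: float = math.nan
    p: float = math.nan
    n_permutations: int = 0
    note: str = ""


def _sequence_contrasts(seq: MimeticSequence) -> Dict[str, float]:
    """Per-variable mean |difference| over consecutive measured pairs."""
    out: Dict[str, float] = {}
    if seq.acoustics is None:
        return out
    vals = {
        v: [
            getattr(a, v) if a is not None else math.nan
            for a in seq.acoustics
        ]
        for v in ACOUSTIC_VARIABLES
    }
    for v, xs in vals.items():
        diffs = [
            abs(b - a)
            for a, b in zip(xs, xs[1:])
            if not (math.isnan(a) or math.isnan(b))
        ]
        if diffs:
            out[v] = float(np.mean(diffs))
    return out


def _sequence_pair_diffs(seq: MimeticSequence) -> Dict[str, list]:
    """Per-variable list of |consecutive differences| (pooled-pairs mode)."""
    out: Dict[str, list] = {v: [] for v in ACOUSTIC_VARIABLES}
    if seq.acoustics is None:
        return out
    for v in ACOUSTIC_VARIABLES:
        xs = [getattr(a, v) if a is not None else math.nan for a in seq.acoustics]
        out[v] = [
            abs(b - a)
            for a, b in zip(xs, xs[1:])
            if not (math.isnan(a) or math.isnan(b))
        ]
    return out


def _grouped_contrast_means(
    sequences: Sequence[MimeticSequence],
    group_by: Optional[str],
    *,
    pooled_pairs: bool = False,
) -> Dict[str, Dict[str, tuple[float, float, int]]]:
    """{group: {variable: (mean, sd, n)}} of consecutive-unit contrasts.

    Default is two-stage averaging (within sequence, then across
    sequences; n counts sequences); with ``pooled_pairs`` every
    consecutive pair contributes one value directly (n counts pairs).
    """
    per_group: Dict[str, Dict[str, list]] = {}
    for seq in sequences:
        if pooled_pairs:
            contrasts = _sequence_pair_diffs(seq)
        else:
            contrasts = _sequence_contrasts(seq)
        groups = [ALL_GROUP]
        if group_by == "population":
            groups.append(seq.population_id)
        for g in groups:
            store = per_group.setdefault(g, {v: [] for v in ACOUSTIC_VARIABLES})
            for v, val in contrasts.items():
                if pooled_pairs:
                    store[v].extend(val)
                else:
                    store[v].append(val)
    out: Dict[str, Dict[str, tuple[float, float, int]]] = {}
    for g, store in per_group.items():
        out[g] = {}
        for v in ACOUSTIC_VARIABLES:
            xs = store[v]
            if not xs:
                out[g][v] = (math.nan, math.nan, 0)
            else:
                arr = np.asarray(xs)
                out[g][v] = (
                    float(arr.mean()),
                    float(arr.std(ddof=1)) if len(arr) > 1 else math.nan,
                    len(arr),
                )
    return out


def acoustic_contrast(
    sequences: Sequence[MimeticSequence],
    group_by: Optional[str] = "population",
    *,
    pooled_pairs: bool = False,
) -> List[ContrastResult]:
    """Observed consecutive-unit acoustic contrast per variable and grouping.

    Two-stage averaging: mean absolute consecutive difference within each
    sequence, then mean and sd of those per-sequence values across
    sequences. Sequences with fewer than two measured units for a variable
    contribute nothing to that variable (logged). ``group_by="population"``
    adds per-population rows alongside the overall ("all") rows.
    """
    measured = [s for s in sequences if s.acoustics is not None]
    skipped = len(sequences) - len(measured)
    if skipped:
        logger.info("%d sequences without acoustic measurements excluded", skipped)
    grouped = _grouped_contrast_means(measured, group_by, pooled_pairs=pooled_pairs)
    results = []
    for g in sorted(grouped):
        for v in ACOUSTIC_VARIABLES:
            mean, sd, n = grouped[g][v]
            results.append(
                ContrastResult(
                    variable=v, group=g, observed_mean=mean, observed_sd=sd,
                    n_sequences=n,
                )
            )
    return results


def contrast_permutation_test(
    sequences: Sequence[MimeticSequence],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    group_by: Optional[str] = "population",
) -> List[ContrastResult]:
    """Acoustic contrast vs. the within-sequence order-shuffle null.

    Units are shuffled within each sequence with their measurements
    attached; the grouped means are recomputed per permutation and each
    (variable, grouping) cell gets a z score and two-sided p.
    """
    measured = [s for s in sequences if s.acoustics is not None]
    if not measured:
        raise ValueError("no sequences carry acoustic measurements")
    observed = _grouped_contrast_means(measured, group_by)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    null: Dict[str, Dict[str, np.ndarray]] = {
        g: {v: np.empty(n_perm) for v in ACOUSTIC_VARIABLES} for g in observed
    }
    for k in range(n_perm):
        rng = np.random.default_rng(children[k])
        shuffled = [_shuffle_sequence(s, rng) for s in measured]
        got = _grouped_contrast_means(shuffled, group_by)
        for g in observed:
            for v in ACOUSTIC_VARIABLES:
                null[g][v][k] = got.get(g, {}).get(v, (math.nan,))[0]
    results = []
    for g in sorted(observed):
        for v in ACOUSTIC_VARIABLES:
            mean, sd, n = observed[g][v]
            if math.isnan(mean):
                results.append(
                    ContrastResult(
                        variable=v, group=g, observed_mean=mean, observed_sd=sd,
                        n_sequences=n, n_permutations=n_perm,
                        note="no measured consecutive pairs",
                    )
                )
                continue
            base = _z_test(mean, null[g][v][~np.isnan(null[g][v])])
            results.append(
                ContrastResult(
                    variable=v, group=g, observed_mean=mean, observed_sd=sd,
                    n_sequences=n, perm_mean=base.perm_mean, perm_sd=base.perm_sd,
                    z=base.z, p=base.p, n_permutations=n_perm, note=base.note,
                )
            )
    return results


def contrast_table(results: List[ContrastResult]):
    """Arrange contrast results as a measured/expected/z/p table per group."""
    import pandas as pd

    rows = []
    for stat in ("measured", "measured_sd", "expected", "z", "p"):
        for g in sorted({r.group for r in results}):
            row: dict = {"population": g, "statistic": stat}
            for r in results:
                if r.group != g:
                    continue
                row[r.variable] = {
                    "measured": r.observed_mean,
                    "measured_sd": r.observed_sd,
                    "expected": r.perm_mean,
                    "z": r.z,
                    "p": r.p,
                }[stat]
            rows.append(row)
    return pd.DataFrame(rows)
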