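"""Cutting bouts into comparable sequences.

Continuous display bouts have no obvious sequence boundaries, so bouts are
split at every occurrence of a single "split unit" — the mimetic unit type
with the most consistently high relative frequency across all birds. Each
retained sequence therefore begins with the split unit. A leading fragment
that does not begin with the split unit is dropped, as is the final
sequence of each bout (it may be truncated by recording conditions).
Species-specific whistle songs and their solitary introductory elements are
then removed from within the retained sequences.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    MIMETIC_CLASSES,
    REMOVED_CLASSES,
    Bout,
    MimeticSequence,
    UnitClass,
)

logger = logging.getLogger(__name__)


@dataclass
class SegmentationReport:
    """Accounting of what segmentation kept, dropped and removed."""

    split_unit: str
    retained_per_bird: dict[str, int] = field(default_factory=dict)
    dropped_per_bird: dict[str, int] = field(default_factory=dict)
    removed_whistle_units: int = 0
    removed_introductory_units: int = 0
    dropped_empty_after_filter: int = 0

    @property
    def n_sequences(self) -> int:
        return sum(self.retained_per_bird.values())

    def as_dict(self) -> dict:
        return {
            "split_unit": self.split_unit,
            "n_sequences": self.n_sequences,
            "retained_per_bird": dict(sorted(self.retained_per_bird.items())),
            "dropped_per_bird": dict(sorted(self.dropped_per_bird.items())),
            "removed_whistle_units": self.removed_whistle_units,
            "removed_introductory_units": self.removed_introductory_units,
            "dropped_empty_after_filter": self.dropped_empty_after_filter,
        }


def choose_split_unit(bouts: Iterable[Bout]) -> str:
    """Pick the mimetic unit code with the largest minimum per-bird frequency.

    For each bird the relative frequency of a code is its count divided by
    the bird's total number of mimetic units. Only codes present in every
    bird's bouts are candidates; the winner maximizes the minimum per-bird
    relative frequency. Ties are broken by highest mean relative frequency,
    then lexicographically, so the choice is deterministic.
    """
    per_bird_counts: dict[str, Counter] = defaultdict(Counter)
    per_bird_total: Counter = Counter()
    for bout in bouts:
        for u in bout.units:
            if u.unit_class in MIMETIC_CLASSES:
                per_bird_counts[bout.bird_id][u.code] += 1
                per_bird_total[bout.bird_id] += 1
    if not per_bird_counts:
        raise ValueError("no mimetic units found in any bout")
    for bird, total in per_bird_total.items():
        if total == 0:
            raise ValueError(f"bird {bird!r} has no mimetic units")
    birds = list(per_bird_counts)
    shared = set.intersection(*(set(per_bird_counts[b]) for b in birds))
    if not shared:
        raise ValueError(
            "no mimetic unit code occurs in every bird; supply "
            "split_unit_override in the configuration"
        )
    def score(code: str) -> tuple[float, float, str]:
        freqs = [per_bird_counts[b][code] / per_bird_total[b] for b in birds]
        # ties: highest mean relative frequency, then lexicographically first
        return (-min(freqs), -(sum(freqs) / len(freqs)), code)

    return min(shared, key=score)


def segment_bout(
    bout: Bout,
    split_unit: str,
    *,
    drop_last: bool = True,
    source_bout: int = 0,
) -> list[MimeticSequence]:
    """Cut a bout immediately before every occurrence of ``split_unit``.

    The leading fragment is dropped when it does not begin with the split
    unit; the final sequence is dropped by default (truncation risk at the
    end of a recording). Every retained sequence starts with the split unit.
    Segmentation is a partition: before any dropping, the concatenation of
    all fragments reconstructs the bout.
    """
    codes = bout.codes
    cuts = [i for i, c in enumerate(codes) if c == split_unit]
    if not cuts:
        logger.warning(
            "bout of bird %s contains no split unit %r; whole bout dropped",
            bout.bird_id,
            split_unit,
        )
        return []
    bounds = ([0] if cuts[0] != 0 else []) + cuts + [len(codes)]
    fragments = [
        (start, codes[start:stop])
        for start, stop in zip(bounds, bounds[1:])
    ]
    retained = []
    for pos, (start, frag) in enumerate(fragments):
        if not frag:
            continue
        if frag[0] != split_unit:
            continue  # leading fragment
        retained.append((pos, start, len(frag)))
    if drop_last and retained:
        retained = retained[:-1]
    out = []
    for pos, start, n in retained:
        stop = start + n
        out.append(
            MimeticSequence(
                bird_id=bout.bird_id,
                population_id=bout.population_id,
                codes=tuple(codes[start:stop]),
                unit_classes=tuple(u.unit_class for u in bout.units[start:stop]),
                acoustics=tuple(u.acoustics for u in bout.units[start:stop]),
                source_bout=source_bout,
                position=pos,
            )
        )
    return out


def filter_sequence(
    seq: MimeticSequence, *, keep_unknown: bool = True
) -> Optional[MimeticSequence]:
    """Remove whistle-song and introductory-element units from a sequence.

    Order of the remaining units is preserved. Unknown-class units are kept
    by default. Returns ``None`` (caller drops, with a log entry) if
    nothing remains.
    """
    keep = [
        i
        for i, c in enumerate(seq.unit_classes)
        if c not in REMOVED_CLASSES and (keep_unknown or c is not UnitClass.UNKNOWN)
    ]
    if not keep:
        logger.warning(
            "sequence %s/#%d empty after filtering; dropped",
            seq.bird_id,
            seq.position,
        )
        return None
    return MimeticSequence(
        bird_id=seq.bird_id,
        population_id=seq.population_id,
        codes=tuple(seq.codes[i] for i in keep),
        unit_classes=tuple(seq.unit_classes[i] for i in keep),
        acoustics=(
            tuple(seq.acoustics[i] for i in keep) if seq.acoustics is not None else None
        ),
        source_bout=seq.source_bout,
        position=seq.position,
    )


def segment_dataset(
    bouts_by_bird: Mapping[str, Sequence[Bout]],
    *,
    split_unit: Optional[str] = None,
    drop_last: str = "per_bout",
    keep_unknown: bool = True,
    min_sequence_length: int = 1,
) -> tuple[list[MimeticSequence], SegmentationReport]:
    """Segment and filter all birds' bouts into the analysis sequence set.

    ``drop_last`` is ``"per_bout"`` (default: drop the final sequence of
    every bout) or ``"per_bird"`` (drop only the final sequence of each
    bird's last bout — relevant when one bird's singing was recorded over
    several sessions that are effectively one continuous sample).
    """
    if drop_last not in ("per_bout", "per_bird"):
        raise ValueError("drop_last must be 'per_bout' or 'per_bird'")
    all_bouts = [b for bouts in bouts_by_bird.values() for b in bouts]
    chosen = split_unit or choose_split_unit(all_bouts)
    report = SegmentationReport(split_unit=chosen)
    out: list[MimeticSequence] = []
    for bird, bouts in bouts_by_bird.items():
        retained_bird: list[MimeticSequence] = []
        dropped = 0
        for k, bout in enumerate(bouts):
            per_bout_drop = drop_last == "per_bout" or k == len(bouts) - 1
            segs = segment_bout(
                bout, chosen, drop_last=per_bout_drop, source_bout=k
            )
            n_candidates = sum(1 for c in bout.codes if c == chosen)
            dropped += n_candidates - len(segs)
            retained_bird.extend(segs)
        kept = 0
        for seq in retained_bird:
            pre = len(seq)
            filtered = filter_sequence(seq, keep_unknown=keep_unknown)
            if filtered is None:
                report.dropped_empty_after_filter += 1
                dropped += 1
                continue
            removed = pre - len(filtered)
            report.removed_whistle_units += sum(
                1 for c in seq.unit_classes if c is UnitClass.WHISTLE_SONG
            )
            report.removed_introductory_units += sum(
                1 for c in seq.unit_classes if c is UnitClass.INTRODUCTORY_ELEMENT
            )
            del removed
            if len(filtered) < min_sequence_length:
                dropped += 1
                continue
            out.append(filtered)
            kept += 1
        report.retained_per_bird[bird] = kept
        report.dropped_per_bird[bird] = dropped
    return out, report
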