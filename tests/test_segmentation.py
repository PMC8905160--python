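"""Split-unit choice, bout segmentation and sequence filtering."""

import numpy as np
import pytest

import vocalseq as vs
from vocalseq.segmentation import choose_split_unit, filter_sequence, segment_bout
from vocalseq.types import Bout, UnitClass, UnitRecord

from conftest import mk_seq


def bout_from_codes(codes, bird="B1", pop="P1", classes=None):
    if classes is None:
        classes = [UnitClass.MIMETIC_VOCAL] * len(codes)
    units = [
        UnitRecord(code=c, unit_class=k, begin_time=float(i), end_time=i + 0.5)
        for i, (c, k) in enumerate(zip(codes, classes))
    ]
    return Bout(bird_id=bird, population_id=pop, units=units)


class TestChooseSplitUnit:
    def test_largest_minimum_frequency_wins(self):
        # min per-bird frequency: d = min(0.20, 0.25) = 0.20,
        # A = min(0.30, 0.01) = 0.01, B = min(0.50, 0.04) = 0.04;
        # C is not shared, so d wins despite A and B peaking higher
        b1 = bout_from_codes(["d"] * 20 + ["A"] * 30 + ["B"] * 50)
        b2 = bout_from_codes(
            ["d"] * 25 + ["A"] * 1 + ["B"] * 4 + ["C"] * 70, bird="B2"
        )
        assert choose_split_unit([b1, b2]) == "d"

    def test_single_bird_returns_most_frequent(self):
        b = bout_from_codes(["x", "y", "y", "y", "z"])
        assert choose_split_unit([b]) == "y"

    def test_brute_force_scan_on_many_birds(self, rng):
        # 25 birds; code 'q' planted with highest minimum relative frequency
        codes_pool = [f"c{i}" for i in range(12)]
        bouts = []
        for b in range(25):
            n = 120
            counts = rng.multinomial(n - 30, np.ones(12) / 12)
            codes = [c for c, k in zip(codes_pool, counts) for _ in range(k)]
            codes += ["q"] * 30  # 25% everywhere, well above any other minimum
            rng.shuffle(codes)
            bouts.append(bout_from_codes(codes, bird=f"B{b}"))
        # independent brute-force oracle over all shared codes
        from collections import Counter

        freqs = {}
        for bout in bouts:
            c = Counter(bout.codes)
            total = sum(c.values())
            for code, k in c.items():
                freqs.setdefault(code, {})[bout.bird_id] = k / total
        shared = [c for c, f in freqs.items() if len(f) == 25]
        oracle = max(shared, key=lambda c: min(freqs[c].values()))
        assert choose_split_unit(bouts) == oracle == "q"

    def test_no_shared_code_raises(self):
        b1 = bout_from_codes(["a", "b"])
        b2 = bout_from_codes(["c", "e"], bird="B2")
        with pytest.raises(ValueError, match="override"):
            choose_split_unit([b1, b2])


class TestSegmentBout:
    def test_leading_and_last_fragments_dropped(self):
        bout = bout_from_codes(list("XYdABdCDdEF"))
        segs = segment_bout(bout, "d")
        assert [s.codes for s in segs] == [("d", "A", "B"), ("d", "C", "D")]

    def test_two_occurrences_keep_only_first(self):
        bout = bout_from_codes(list("dAdB"))
        segs = segment_bout(bout, "d")
        assert [s.codes for s in segs] == [("d", "A")]

    def test_all_retained_start_with_split_unit(self, rng):
        codes = [str(rng.integers(0, 9)) for _ in range(200)]
        bout = bout_from_codes(codes)
        segs = segment_bout(bout, "3")
        assert all(s.codes[0] == "3" for s in segs)

    def test_matches_independent_index_scan(self, rng):
        # random 200-unit bout; verify against a brute-force index scan
        codes = list(rng.choice(list("dABCEFG"), size=200, p=[0.06] + [0.94 / 6] * 6))
        bout = bout_from_codes(codes)
        segs = segment_bout(bout, "d")
        idx = [i for i, c in enumerate(codes) if c == "d"]
        expected = [
            tuple(codes[a:b]) for a, b in zip(idx, idx[1:] + [len(codes)])
        ][:-1]  # last sequence dropped
        assert [s.codes for s in segs] == expected

    def test_partition_before_dropping(self, rng):
        # retained + dropped fragments reconstruct the bout exactly
        codes = list(rng.choice(list("dXY"), size=60))
        bout = bout_from_codes(codes)
        if "d" not in codes:
            codes[0] = "d"
            bout = bout_from_codes(codes)
        segs = segment_bout(bout, "d", drop_last=False)
        idx = codes.index("d")
        reconstructed = codes[:idx] + [c for s in segs for c in s.codes]
        assert reconstructed == codes

    def test_missing_split_unit_drops_bout(self, caplog):
        bout = bout_from_codes(list("ABC"))
        assert segment_bout(bout, "d") == []


class TestFilterSequence:
    def test_whistles_removed_order_preserved(self):
        seq = mk_seq(
            "B1", "P1", ["d", "A", "W", "B"],
            classes=[
                UnitClass.MIMETIC_VOCAL,
                UnitClass.MIMETIC_VOCAL,
                UnitClass.WHISTLE_SONG,
                UnitClass.MIMETIC_VOCAL,
            ],
        )
        out = filter_sequence(seq)
        assert out.codes == ("d", "A", "B")

    def test_unknown_units_retained_by_default(self):
        seq = mk_seq(
            "B1", "P1", ["d", "u"],
            classes=[UnitClass.MIMETIC_VOCAL, UnitClass.UNKNOWN],
        )
        assert filter_sequence(seq).codes == ("d", "u")

    def test_all_whistle_sequence_dropped(self):
        seq = mk_seq(
            "B1", "P1", ["W", "W"],
            classes=[UnitClass.WHISTLE_SONG, UnitClass.WHISTLE_SONG],
        )
        assert filter_sequence(seq) is None

    def test_study_scale_removal_counts(self, rng):
        # scatter exactly 314 whistles and 14 introductory elements over a
        # large sequence set; segmentation accounting must find all 328
        base = [list("dABCE") for _ in range(500)]
        units_per_bird = []
        whistle_slots = 314
        intro_slots = 14
        flat = []
        for k, codes in enumerate(base):
            classes = [UnitClass.MIMETIC_VOCAL] * len(codes)
            flat.append((codes, classes))
        i = 0
        while whistle_slots or intro_slots:
            codes, classes = flat[i % len(flat)]
            if whistle_slots:
                codes.append("W")
                classes.append(UnitClass.WHISTLE_SONG)
                whistle_slots -= 1
            elif intro_slots:
                codes.append("i")
                classes.append(UnitClass.INTRODUCTORY_ELEMENT)
                intro_slots -= 1
            i += 1
        # build one bout per 100 sequences, plus a trailing sacrificial
        # rendition per bout that segmentation drops
        bouts = {}
        for b in range(5):
            chunk = flat[b * 100 : (b + 1) * 100]
            codes = [c for cs, ks in chunk for c in cs] + ["d", "Z"]
            classes = [k for cs, ks in chunk for k in ks] + [
                UnitClass.MIMETIC_VOCAL, UnitClass.MIMETIC_VOCAL,
            ]
            bouts[f"B{b}"] = [bout_from_codes(codes, bird=f"B{b}", classes=classes)]
        seqs, report = vs.segment_dataset(bouts, split_unit="d")
        assert report.removed_whistle_units == 314
        assert report.removed_introductory_units == 14
        assert all("W" not in s.codes and "i" not in s.codes for s in seqs)


class TestSegmentDataset:
    def test_accounting_identity(self, small_dataset):
        seqs, report = vs.segment_dataset(small_dataset.bouts_by_bird)
        for bird in report.retained_per_bird:
            candidates = sum(
                sum(1 for c in bout.codes if c == report.split_unit)
                for bout in small_dataset.bouts_by_bird[bird]
            )
            assert (
                report.retained_per_bird[bird] + report.dropped_per_bird[bird]
                == candidates
            )

    def test_idempotent_and_deterministic(self, small_dataset):
        a, _ = vs.segment_dataset(small_dataset.bouts_by_bird)
        b, _ = vs.segment_dataset(small_dataset.bouts_by_bird)
        assert [s.codes for s in a] == [s.codes for s in b]

    def test_recovers_generator_renditions(self, small_dataset):
        seqs, _ = vs.segment_dataset(small_dataset.bouts_by_bird)
        truth = vs.sequences_from_truth(small_dataset)
        got = {}
        for s in seqs:
            got.setdefault(s.bird_id, []).append(s.codes)
        want = {}
        for s in truth:
            want.setdefault(s.bird_id, []).append(s.codes)
        assert got == want

    def test_per_bird_last_drop_keeps_more(self):
        bouts = {
            "B1": [
                bout_from_codes(list("dABdCD")),
                bout_from_codes(list("dEFdGH")),
            ]
        }
        per_bout, _ = vs.segment_dataset(bouts, split_unit="d", drop_last="per_bout")
        per_bird, _ = vs.segment_dataset(bouts, split_unit="d", drop_last="per_bird")
        assert len(per_bird) == len(per_bout) + 1
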