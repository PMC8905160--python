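"""Synthetic culturally structured vocal-sequence datasets.

Emulates a multi-population study of song-sequence sharing: a hierarchy
of sequence *templates* is generated (one global template, per-population
templates derived by divergence edits, per-bird templates by
within-population edits) and each sung rendition of a bird's template
receives further per-symbol rendition edits. All edits are symbol-level
substitutions, insertions and deletions with equal shares — the simplest
generative process whose output is naturally analysed with edit-distance
methods. Two stylistic forces can be switched on: *repeat suppression*
(a draw that duplicates its predecessor is resampled with the given
probability, producing immediate variety) and *contrast bias* (successor
symbols are preferred in proportion to ``exp(bias * acoustic distance)``
from their predecessor, producing high acoustic contrast between
consecutive units).

Each unit type carries an acoustic profile (mean of the seven
measurements plus a per-variable noise sd); sampled units draw their
measurements from that profile, so the organization analyses see
unit-type-anchored acoustics exactly as a measured dataset would.

Every rendition begins with a dedicated, globally shared "anchor" unit
(the split unit), and bouts are emitted with a truncated trailing
rendition and occasionally a leading fragment, so the segmentation stage
has realistic work to do. Default scales follow a 5-population x 5-male
study with ~18 sequences per male of mean length ~15 units drawn from
15-37 unit types per population, neighbouring birds ~300 m apart and
populations tens of kilometres apart.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    ACOUSTIC_VARIABLES,
    AcousticMeasures,
    Bout,
    MimeticSequence,
    StudyDesign,
    UnitClass,
    UnitRecord,
)

#: code of the anchor (split) unit present in every bird's repertoire
ANCHOR_CODE = "d"
WHISTLE_CODE = "W"
INTRO_CODE = "i"

_CODE_CHARS = (
    "abcefghjklmnopqrstuvwxyz"  # 'd' and 'i' reserved
    "ABCDEFGHJKLMNOPQRSTUVXYZ0123456789"  # 'I' and 'W' reserved
)


@dataclass
class SyntheticConfig:
    """Tunable parameters of the generator.

    Scale defaults mirror the structure of a range-wide field study
    (populations, birds per population, sequences per bird, sequence
    length and repertoire-size distributions); transmission-fidelity
    rates are per-symbol edit probabilities at each level of the
    template hierarchy.
    """

    n_populations: int = 5
    birds_per_population: int = 5
    sequences_per_bird_mean: float = 17.9
    sequences_per_bird_sd: float = 5.97
    min_sequences_per_bird: int = 3
    alphabet_size_range: Tuple[int, int] = (15, 37)
    global_pool_size: int = 60
    template_length_mean: float = 15.1
    template_length_sd: float = 7.15
    template_length_bounds: Tuple[int, int] = (3, 58)
    between_population_divergence: float = 0.5
    within_population_noise: float = 0.12
    rendition_noise: float = 0.18
    repeat_suppression: float = 0.95
    contrast_bias: float = 1.5
    whistle_insertion_rate: float = 0.045
    introductory_rate: float = 0.003
    vocal_fraction: float = 0.8
    acoustic_noise_scale: float = 0.05
    neighbour_spacing_m: float = 300.0
    population_spacing_m: float = 30000.0
    measure_fraction: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "between_population_divergence",
            "within_population_noise",
            "rendition_noise",
            "repeat_suppression",
            "whistle_insertion_rate",
            "introductory_rate",
            "vocal_fraction",
            "measure_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.alphabet_size_range
        if lo < 2 or hi < lo:
            raise ValueError("alphabet_size_range must be (lo, hi) with 2 <= lo <= hi")
        if self.global_pool_size < hi:
            raise ValueError(
                "alphabet too small: global_pool_size must cover the largest "
                "population alphabet"
            )
        blo, bhi = self.template_length_bounds
        if blo < 1 or bhi < blo:
            raise ValueError("template_length_bounds must be (lo, hi), lo >= 1")


@dataclass
class SyntheticDataset:
    """Generated bouts plus the design and the ground truth that made them."""

    bouts_by_bird: Dict[str, List[Bout]]
    design: StudyDesign
    truth: dict


def _code_for(index: int) -> str:
    if index == 0:
        return ANCHOR_CODE
    index -= 1
    chars = _CODE_CHARS
    if index < len(chars):
        return chars[index]
    return chars[index % len(chars)] + str(index // len(chars))


def _acoustic_profiles(
    n_types: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-type mean vectors and noise sds for the seven variables.

    Scales follow typical passerine spectrogram measurements: peak
    frequency ~1.5-5.5 kHz, bandwidths up to a few kHz, durations up to
    ~1.2 s, entropies of a few bits and peak powers of tens of dB.
    """
    peak = rng.uniform(1.5, 5.5, n_types)
    low = np.clip(peak - rng.uniform(0.3, 1.8, n_types), 0.1, None)
    high = low + rng.uniform(0.5, 4.0, n_types)
    bw = high - low
    dur = rng.uniform(0.1, 1.2, n_types)
    ent = rng.uniform(2.0, 6.0, n_types)
    power = rng.uniform(40.0, 75.0, n_types)
    means = np.column_stack([peak, low, high, bw, dur, ent, power])
    spreads = np.ptp(means, axis=0)
    spreads[spreads == 0] = 1.0
    sds = np.tile(spreads, (n_types, 1))
    return means, sds


class _Sampler:
    """Draws successor symbols with repeat suppression and contrast bias."""

    def __init__(self, cfg: SyntheticConfig, profiles: np.ndarray):
        self.cfg = cfg
        # standardized profile space for contrast distances
        mu = profiles.mean(axis=0)
        sd = profiles.std(axis=0)
        sd[sd == 0] = 1.0
        self.zprof = (profiles - mu) / sd

    def draw(
        self,
        alphabet: np.ndarray,
        prev: Optional[int],
        rng: np.random.Generator,
    ) -> int:
        cfg = self.cfg
        weights = np.ones(len(alphabet))
        if prev is not None and cfg.contrast_bias > 0:
            d = np.linalg.norm(
                self.zprof[alphabet] - self.zprof[prev], axis=1
            )
            d = d / (d.max() or 1.0)
            weights = np.exp(cfg.contrast_bias * d)
        if prev is not None and cfg.repeat_suppression > 0:
            dup = alphabet == prev
            weights = np.where(dup, weights * (1.0 - cfg.repeat_suppression), weights)
        total = weights.sum()
        if total <= 0:
            weights = np.ones(len(alphabet))
            total = weights.sum()
        return int(rng.choice(alphabet, p=weights / total))


def _truncated_normal_int(
    mean: float, sd: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    for _ in range(1000):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    return int(min(max(round(mean), lo), hi))


def _suppress_repeats(
    out: List[int],
    alphabet: np.ndarray,
    sampler: _Sampler,
    rng: np.random.Generator,
) -> List[int]:
    """Resample symbols that duplicate their predecessor.

    Edits act locally (a drawn symbol only avoids duplicating the symbol
    before it), so deletions and insertions can still juxtapose two copies
    of one unit type. This repair pass applies the suppression probability
    to every such juxtaposition, resampling from the alphabet minus both
    neighbours so no new adjacency is created.
    """
    s = sampler.cfg.repeat_suppression
    if s <= 0:
        return out
    for k in range(1, len(out)):
        if out[k] != out[k - 1] or rng.random() >= s:
            continue
        banned = {out[k - 1]}
        if k + 1 < len(out):
            banned.add(out[k + 1])
        candidates = np.array([a for a in alphabet if a not in banned])
        if len(candidates):
            out[k] = sampler.draw(candidates, out[k - 1], rng)
    return out


def _apply_edits(
    seq: List[int],
    rate: float,
    alphabet: np.ndarray,
    sampler: _Sampler,
    rng: np.random.Generator,
) -> List[int]:
    """Per-symbol substitution/insertion/deletion edits with equal shares.

    Position 0 (the anchor unit) is never edited so segmentation structure
    is preserved; the anchor is also never drawn as a replacement.
    """
    out = [seq[0]]
    for k in range(1, len(seq)):
        sym = seq[k]
        if rng.random() < rate:
            kind = rng.integers(3)
            prev = out[-1] if out else None
            if kind == 0:  # substitution
                out.append(sampler.draw(alphabet, prev, rng))
            elif kind == 1:  # insertion (before current symbol)
                out.append(sampler.draw(alphabet, prev, rng))
                out.append(sym)
            # kind == 2: deletion — drop the symbol
        else:
            out.append(sym)
    if len(out) < 2:
        out.append(int(alphabet[0]))
    return _suppress_repeats(out, alphabet, sampler, rng)


def generate_dataset(
    config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Generate a full hierarchical dataset with its ground-truth record.

    ``seed`` overrides ``config.seed``. The truth record contains the
    templates at every level, the realized per-bird rendition lists
    (pre-whistle-insertion), the acoustic profiles and all rates, enabling
    parameter-recovery tests.
    """
    cfg = config or SyntheticConfig()
    master = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(master)

    n_types = cfg.global_pool_size + 1  # +1 for the anchor at index 0
    profiles, profile_sds = _acoustic_profiles(n_types, rng)
    profile_sds = profile_sds * cfg.acoustic_noise_scale
    sampler = _Sampler(cfg, profiles)
    vocal = rng.random(n_types) < cfg.vocal_fraction
    vocal[0] = True  # the anchor is a vocal unit

    lo_a, hi_a = cfg.alphabet_size_range
    core_size = lo_a
    pool = np.arange(1, n_types)
    core = rng.choice(pool, size=core_size - 1, replace=False)

    # global template: anchor followed by contrast-biased draws from the core
    g_len = _truncated_normal_int(
        cfg.template_length_mean,
        cfg.template_length_sd,
        *cfg.template_length_bounds,
        rng,
    )
    g_template = [0]
    for _ in range(g_len - 1):
        g_template.append(sampler.draw(core, g_template[-1], rng))

    bouts_by_bird: Dict[str, List[Bout]] = {}
    bird_pop: Dict[str, str] = {}
    coords: Dict[str, Tuple[float, float]] = {}
    truth: dict = {
        "config": dataclasses.asdict(cfg),
        "seed": master,
        "global_template": list(map(int, g_template)),
        "population_templates": {},
        "bird_templates": {},
        "renditions": {},
        "alphabets": {},
        "profiles": profiles.tolist(),
        "vocal_types": vocal.tolist(),
        "codes": [_code_for(t) for t in range(n_types)],
    }

    base_lat, base_lon = -28.2, 153.1
    m_per_deg = 111320.0
    for p in range(cfg.n_populations):
        pop_id = f"P{p + 1}"
        a_size = int(rng.integers(lo_a, hi_a + 1))
        extra = rng.choice(
            np.setdiff1d(pool, core), size=a_size - core_size, replace=False
        )
        alphabet = np.concatenate([core, extra])
        truth["alphabets"][pop_id] = sorted(int(x) for x in alphabet)
        pop_template = _apply_edits(
            g_template, cfg.between_population_divergence, alphabet, sampler, rng
        )
        truth["population_templates"][pop_id] = list(map(int, pop_template))
        pop_lat = base_lat + (p * cfg.population_spacing_m) / m_per_deg
        pop_lon = base_lon + (p % 2) * 0.05
        for b in range(cfg.birds_per_population):
            bird_id = f"{pop_id}_B{b + 1}"
            bird_pop[bird_id] = pop_id
            jitter = cfg.neighbour_spacing_m * (b + rng.uniform(0.3, 1.2))
            coords[bird_id] = (
                pop_lat + jitter / m_per_deg,
                pop_lon + (rng.uniform(-1, 1) * cfg.neighbour_spacing_m) / m_per_deg,
            )
            bird_template = _apply_edits(
                pop_template, cfg.within_population_noise, alphabet, sampler, rng
            )
            truth["bird_templates"][bird_id] = list(map(int, bird_template))
            n_seq = _truncated_normal_int(
                cfg.sequences_per_bird_mean,
                cfg.sequences_per_bird_sd,
                cfg.min_sequences_per_bird,
                10**6,
                rng,
            )
            renditions = [
                _apply_edits(bird_template, cfg.rendition_noise, alphabet, sampler, rng)
                for _ in range(n_seq + 1)
            ]
            # final rendition truncated: it will be dropped by segmentation
            last = renditions[-1]
            cut = int(rng.integers(1, max(2, len(last))))
            renditions[-1] = last[:cut]
            truth["renditions"][bird_id] = [list(map(int, r)) for r in renditions]
            units: List[UnitRecord] = []
            t = 0.0
            symbol_stream: List[Tuple[int, UnitClass]] = []
            if rng.random() < 0.5:
                # leading fragment: tail of a rendition, no anchor
                frag = _apply_edits(bird_template, cfg.rendition_noise, alphabet, sampler, rng)
                tail = frag[1:][-int(rng.integers(1, 5)):]
                symbol_stream.extend(
                    (s, UnitClass.MIMETIC_VOCAL if vocal[s] else UnitClass.MIMETIC_NONVOCAL)
                    for s in tail
                )
            for r in renditions:
                for s in r:
                    symbol_stream.append(
                        (s, UnitClass.MIMETIC_VOCAL if vocal[s] else UnitClass.MIMETIC_NONVOCAL)
                    )
                    if rng.random() < cfg.whistle_insertion_rate:
                        symbol_stream.append((-1, UnitClass.WHISTLE_SONG))
                        if rng.random() < cfg.introductory_rate / max(
                            cfg.whistle_insertion_rate, 1e-9
                        ):
                            symbol_stream.append((-2, UnitClass.INTRODUCTORY_ELEMENT))
            for s, klass in symbol_stream:
                if s >= 0:
                    code = _code_for(s)
                    mean_vec = profiles[s]
                    sd_vec = profile_sds[s]
                else:
                    code = WHISTLE_CODE if klass is UnitClass.WHISTLE_SONG else INTRO_CODE
                    mean_vec = profiles.mean(axis=0)
                    sd_vec = profile_sds.mean(axis=0)
                acoustics = None
                if rng.random() < cfg.measure_fraction:
                    draw = rng.normal(mean_vec, sd_vec)
                    vals = dict(zip(ACOUSTIC_VARIABLES, draw))
                    vals["low_frequency_5pct"] = max(0.05, vals["low_frequency_5pct"])
                    vals["high_frequency_95pct"] = max(
                        vals["high_frequency_95pct"], vals["low_frequency_5pct"]
                    )
                    vals["bandwidth_90pct"] = (
                        vals["high_frequency_95pct"] - vals["low_frequency_5pct"]
                    )
                    vals["duration_90pct"] = max(0.01, vals["duration_90pct"])
                    acoustics = AcousticMeasures(**vals)
                dur = acoustics.duration_90pct if acoustics else 0.5
                units.append(
                    UnitRecord(
                        code=code,
                        unit_class=klass,
                        begin_time=round(t, 4),
                        end_time=round(t + dur, 4),
                        acoustics=acoustics,
                    )
                )
                t += dur + float(rng.uniform(0.05, 0.4))
            bouts_by_bird[bird_id] = [
                Bout(bird_id=bird_id, population_id=pop_id, units=units)
            ]

    design = StudyDesign(bird_to_population=bird_pop, coordinates=coords)
    return SyntheticDataset(bouts_by_bird=bouts_by_bird, design=design, truth=truth)


def expected_lsi_under_noise(edit_rate: float, length: int) -> float:
    """Closed-form approximation to E[LSI] between a template and one copy.

    With per-symbol edit probability ``r`` the expected edit distance is at
    most ``r * L`` (each edit event costs at most one operation) while
    insertions inflate the longer-length denominator slightly; the
    approximation ``1 - rL / (L + 0.4 * sqrt(2Lr/3))`` is exact at r = 0
    and monotone decreasing in r. Intended for generator sanity checks at
    small rates, not as an analysis statistic.
    """
    if not 0.0 <= edit_rate <= 0.5:
        raise ValueError("edit_rate must be in [0, 0.5]")
    if length < 1:
        raise ValueError("length must be >= 1")
    if edit_rate == 0.0:
        return 1.0
    denom = length + 0.4 * math.sqrt(2.0 * length * edit_rate / 3.0)
    return 1.0 - (edit_rate * length) / denom


def sequences_from_truth(ds: SyntheticDataset) -> List[MimeticSequence]:
    """Ground-truth sequences (pre-whistle, pre-truncation-drop renditions).

    Convenience for tests that want to bypass segmentation; excludes each
    bird's truncated final rendition, mirroring what segmentation retains.
    """
    out = []
    codes = ds.truth["codes"]
    vocal = ds.truth["vocal_types"]
    for bird, rends in ds.truth["renditions"].items():
        pop = ds.design.bird_to_population[bird]
        for k, r in enumerate(rends[:-1]):
            out.append(
                MimeticSequence(
                    bird_id=bird,
                    population_id=pop,
                    codes=tuple(codes[s] for s in r),
                    unit_classes=tuple(
                        UnitClass.MIMETIC_VOCAL if vocal[s] else UnitClass.MIMETIC_NONVOCAL
                        for s in r
                    ),
                    position=k,
                )
            )
    return out
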