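"""Domain types for annotated vocal sequences.

The analysis operates on bouts of vocal mimicry annotated unit-by-unit:
each unit carries a short alphanumeric code identifying its type, a broad
class (mimetic vocal / mimetic non-vocal / species-specific whistle song /
introductory element / unknown) and, optionally, seven spectro-temporal
measurements taken from a spectrogram selection box. Bouts are segmented
into sequences of unit codes which are then compared with edit-distance
methods; the acoustic measurements feed the sequence-organization tests.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple


class UnitClass(enum.Enum):
    """Broad functional class of a vocal unit."""

    MIMETIC_VOCAL = "mimetic_vocal"
    MIMETIC_NONVOCAL = "mimetic_nonvocal"
    WHISTLE_SONG = "whistle_song"
    INTRODUCTORY_ELEMENT = "introductory_element"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: "UnitClass | str") -> "UnitClass":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            raise ValueError(
                f"unrecognised unit class {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from exc


#: classes that count as mimetic units (retained in sequence analyses)
MIMETIC_CLASSES = frozenset(
    {UnitClass.MIMETIC_VOCAL, UnitClass.MIMETIC_NONVOCAL}
)

#: classes removed from sequences before similarity analysis
REMOVED_CLASSES = frozenset(
    {UnitClass.WHISTLE_SONG, UnitClass.INTRODUCTORY_ELEMENT}
)

#: the seven acoustic measurements, in canonical order
ACOUSTIC_VARIABLES: Tuple[str, ...] = (
    "peak_frequency",
    "low_frequency_5pct",
    "high_frequency_95pct",
    "bandwidth_90pct",
    "duration_90pct",
    "aggregate_entropy",
    "peak_power",
)


@dataclass(frozen=True)
class AcousticMeasures:
    """Spectro-temporal measurements of a single unit.

    Frequencies are in kHz, duration in seconds, entropy in bits and
    power in dB, matching the usual spectrogram-measurement conventions.
    """

    peak_frequency: float
    low_frequency_5pct: float
    high_frequency_95pct: float
    bandwidth_90pct: float
    duration_90pct: float
    aggregate_entropy: float
    peak_power: float

    def __post_init__(self) -> None:
        if self.high_frequency_95pct < self.low_frequency_5pct:
            raise ValueError(
                "high_frequency_95pct must be >= low_frequency_5pct "
                f"({self.high_frequency_95pct} < {self.low_frequency_5pct})"
            )
        if self.bandwidth_90pct < 0:
            raise ValueError("bandwidth_90pct must be >= 0")
        if not self.duration_90pct > 0:
            raise ValueError("duration_90pct must be > 0")

    def as_tuple(self) -> Tuple[float, ...]:
        return tuple(getattr(self, v) for v in ACOUSTIC_VARIABLES)


@dataclass(frozen=True)
class UnitRecord:
    """One annotated vocal unit inside a bout."""

    code: str
    unit_class: UnitClass
    model_species: str = ""
    begin_time: Optional[float] = None
    end_time: Optional[float] = None
    acoustics: Optional[AcousticMeasures] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("unit code must be non-empty")
        object.__setattr__(self, "unit_class", UnitClass.coerce(self.unit_class))
        if (
            self.begin_time is not None
            and self.end_time is not None
            and self.end_time < self.begin_time
        ):
            raise ValueError(
                f"end_time < begin_time for unit {self.code!r} "
                f"({self.end_time} < {self.begin_time})"
            )


@dataclass
class Bout:
    """One continuous recording of a single bird, as an ordered unit list.

    Units must be ordered by ``begin_time`` (non-decreasing) when times
    are present; ties keep file order.
    """

    bird_id: str
    population_id: str
    units: list[UnitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev = -math.inf
        for u in self.units:
            if u.begin_time is not None:
                if u.begin_time < prev:
                    raise ValueError(
                        f"bout {self.bird_id}: units not ordered by begin_time"
                    )
                prev = u.begin_time

    def __len__(self) -> int:
        return len(self.units)

    @property
    def codes(self) -> list[str]:
        return [u.code for u in self.units]


@dataclass
class MimeticSequence:
    """One segmented sequence of unit codes for one bird.

    ``codes`` is the ordered list of unit-type tokens; ``unit_classes``
    is the parallel list of classes and ``acoustics`` the parallel list
    of measurements (``None`` where a unit was not measured).
    ``source_bout``/``position`` record where in the bird's recordings
    the sequence came from.
    """

    bird_id: str
    population_id: str
    codes: Tuple[str, ...]
    unit_classes: Tuple[UnitClass, ...]
    acoustics: Optional[Tuple[Optional[AcousticMeasures], ...]] = None
    source_bout: int = 0
    position: int = 0

    def __post_init__(self) -> None:
        self.codes = tuple(self.codes)
        self.unit_classes = tuple(UnitClass.coerce(c) for c in self.unit_classes)
        if len(self.codes) < 1:
            raise ValueError("sequence must contain at least one unit")
        if len(self.unit_classes) != len(self.codes):
            raise ValueError("unit_classes must parallel codes")
        if self.acoustics is not None:
            self.acoustics = tuple(self.acoustics)
            if len(self.acoustics) != len(self.codes):
                raise ValueError("acoustics must parallel codes")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class StudyDesign:
    """Sampling design: which bird belongs to which population, where.

    ``coordinates`` maps bird_id -> (lat, lon) in WGS84 decimal degrees.
    ``population_distances`` is an optional pre-computed square matrix of
    inter-population distances (e.g. resistance-weighted least-cost path
    lengths), as a mapping of (pop_a, pop_b) -> distance or a labelled
    nested mapping; see :mod:`vocalseq.io` for the CSV reader.
    """

    bird_to_population: Mapping[str, str]
    coordinates: Optional[Mapping[str, Tuple[float, float]]] = None
    population_distances: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        if self.coordinates:
            for bird, (lat, lon) in self.coordinates.items():
                if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                    raise ValueError(
                        f"invalid WGS84 coordinate for {bird!r}: ({lat}, {lon})"
                    )

    def population_of(self, bird_id: str) -> str:
        try:
            return self.bird_to_population[bird_id]
        except KeyError as exc:
            raise KeyError(f"bird {bird_id!r} missing from design") from exc

    def validate_sequences(self, sequences: Sequence[MimeticSequence]) -> None:
        missing = {s.bird_id for s in sequences} - set(self.bird_to_population)
        if missing:
            raise KeyError(f"birds missing from design: {sorted(missing)}")
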