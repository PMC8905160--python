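"""Readers and writers for annotation tables, designs and sequence files.

Selection tables are the tab-delimited export of spectrogram annotation
software (one row per selection box, arbitrary extra columns, header names
that vary across versions), so the semantic columns are mapped via a
:class:`SelectionTableColumns` config rather than hard-coded names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import pandas as pd

from .types import (
    ACOUSTIC_VARIABLES,
    AcousticMeasures,
    Bout,
    MimeticSequence,
    StudyDesign,
    UnitClass,
    UnitRecord,
)

logger = logging.getLogger(__name__)


class ColumnConfigError(ValueError):
    """A mandatory column is absent from a selection table."""


class RowParseError(ValueError):
    """A cell in a selection table could not be parsed."""


@dataclass
class SelectionTableColumns:
    """Maps semantic fields to header names of a selection table.

    ``acoustics`` maps each of the seven acoustic variable names (see
    :data:`vocalseq.types.ACOUSTIC_VARIABLES`) to a header name; leave it
    empty to skip acoustic ingestion entirely.
    """

    code: str = "code"
    unit_class: str = "class"
    begin_time: str = "begin_time"
    end_time: str = "end_time"
    model_species: Optional[str] = None
    acoustics: Mapping[str, str] = field(default_factory=dict)


def read_selection_table(
    path: str | Path,
    columns: SelectionTableColumns | None = None,
    *,
    bird_id: str,
    population_id: str,
) -> Bout:
    """Read one tab-delimited selection table into a :class:`Bout`.

    Rows are stably sorted by begin time (ties keep file order). Rows with
    any missing acoustic cell get ``acoustics=None``; the unit itself is
    kept. Raises :class:`ColumnConfigError` for a missing mandatory column
    and :class:`RowParseError` (naming the 1-based data row) for an
    unparsable numeric cell.
    """
    cols = columns or SelectionTableColumns()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for fieldname, header in (
        ("code", cols.code),
        ("unit_class", cols.unit_class),
        ("begin_time", cols.begin_time),
        ("end_time", cols.end_time),
    ):
        if header not in df.columns:
            raise ColumnConfigError(
                f"selection table {path} lacks mandatory column "
                f"{header!r} (mapped from {fieldname!r})"
            )
    for var, header in cols.acoustics.items():
        if var not in ACOUSTIC_VARIABLES:
            raise ColumnConfigError(f"unknown acoustic variable {var!r}")
        if header not in df.columns:
            raise ColumnConfigError(
                f"selection table {path} lacks acoustic column {header!r}"
            )

    def _num(row_idx: int, header: str, value: str | float | None) -> Optional[float]:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        s = str(value).strip()
        if not s:
            return None
        try:
            return float(s)
        except ValueError as exc:
            raise RowParseError(
                f"{path}, data row {row_idx + 1}, column {header!r}: "
                f"cannot parse {value!r} as a number"
            ) from exc

    units: list[UnitRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowmap = dict(zip(df.columns, row))
        begin = _num(i, cols.begin_time, rowmap[cols.begin_time])
        end = _num(i, cols.end_time, rowmap[cols.end_time])
        acoustics = None
        if cols.acoustics:
            vals = {
                var: _num(i, header, rowmap[header])
                for var, header in cols.acoustics.items()
            }
            if len(vals) == len(ACOUSTIC_VARIABLES) and all(
                v is not None for v in vals.values()
            ):
                acoustics = AcousticMeasures(**vals)  # type: ignore[arg-type]
        code = str(rowmap[cols.code]).strip()
        species = ""
        if cols.model_species and cols.model_species in rowmap:
            raw = rowmap[cols.model_species]
            species = "" if pd.isna(raw) else str(raw).strip()
        units.append(
            UnitRecord(
                code=code,
                unit_class=UnitClass.coerce(rowmap[cols.unit_class]),
                model_species=species,
                begin_time=begin,
                end_time=end,
                acoustics=acoustics,
            )
        )
    # stable sort by begin time; untimed rows keep their slot order at the end
    order = sorted(
        range(len(units)),
        key=lambda k: (units[k].begin_time is None, units[k].begin_time or 0.0),
    )
    ties = sum(
        1
        for a, b in zip(order, order[1:])
        if units[a].begin_time is not None
        and units[a].begin_time == units[b].begin_time
    )
    if ties:
        logger.info("%s: %d begin-time ties kept in file order", path, ties)
    return Bout(bird_id=bird_id, population_id=population_id, units=[units[k] for k in order])


_FIELD_SEP = "\t"
_CODE_SEP = ","


def write_sequences(sequences: Sequence[MimeticSequence], path: str | Path) -> None:
    """Write sequences as plain text, one per line.

    Line format: ``bird_id<TAB>population_id<TAB>code,code,...<TAB>class,class,...``.
    Codes containing the delimiter characters raise at write time.
    """
    if not sequences:
        raise ValueError("no sequences to write")
    lines = []
    for seq in sequences:
        for tok in seq.codes:
            if _CODE_SEP in tok or _FIELD_SEP in tok or any(c.isspace() for c in tok):
                raise ValueError(
                    f"unit code {tok!r} contains a delimiter character"
                )
        for ident in (seq.bird_id, seq.population_id):
            if _FIELD_SEP in ident:
                raise ValueError(f"identifier {ident!r} contains a tab")
        lines.append(
            _FIELD_SEP.join(
                (
                    seq.bird_id,
                    seq.population_id,
                    _CODE_SEP.join(seq.codes),
                    _CODE_SEP.join(c.value for c in seq.unit_classes),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sequences(path: str | Path) -> list[MimeticSequence]:
    """Read the plain-text sequence format written by :func:`write_sequences`."""
    sequences = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(_FIELD_SEP)
        if len(parts) not in (3, 4):
            raise ValueError(f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
        bird, pop, codestr = parts[0], parts[1], parts[2]
        codes = tuple(codestr.split(_CODE_SEP))
        if len(parts) == 4 and parts[3]:
            classes = tuple(UnitClass.coerce(c) for c in parts[3].split(_CODE_SEP))
        else:
            classes = tuple(UnitClass.UNKNOWN for _ in codes)
        sequences.append(
            MimeticSequence(
                bird_id=bird, population_id=pop, codes=codes, unit_classes=classes
            )
        )
    return sequences


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a CSV with columns ``bird_id,population_id``."""
    df = pd.read_csv(path, dtype=str)
    if not {"bird_id", "population_id"} <= set(df.columns):
        raise ColumnConfigError(
            f"{path}: expected columns bird_id, population_id"
        )
    return dict(zip(df["bird_id"], df["population_id"]))


def read_coordinates(path: str | Path) -> dict[str, Tuple[float, float]]:
    """Read a CSV with columns ``bird_id,lat,lon`` (WGS84 decimal degrees)."""
    df = pd.read_csv(path)
    if not {"bird_id", "lat", "lon"} <= set(df.columns):
        raise ColumnConfigError(f"{path}: expected columns bird_id, lat, lon")
    return {
        str(r.bird_id): (float(r.lat), float(r.lon))
        for r in df.itertuples(index=False)
    }


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled square distance matrix CSV (labels in first column)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix row and column labels differ")
    return df


def make_design(
    population_map: Mapping[str, str],
    coordinates: Optional[Mapping[str, Tuple[float, float]]] = None,
    population_distances: Optional[pd.DataFrame] = None,
) -> StudyDesign:
    pd_map = None
    if population_distances is not None:
        pd_map = {
            str(a): {str(b): float(population_distances.loc[a, b]) for b in population_distances.columns}
            for a in population_distances.index
        }
    return StudyDesign(
        bird_to_population=dict(population_map),
        coordinates=dict(coordinates) if coordinates else None,
        population_distances=pd_map,
    )
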