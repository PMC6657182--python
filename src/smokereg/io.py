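"""Readers and writers for the registry's tabular record sources.

Three inputs feed a smokers' registry: free-text clinical notes (one row per
patient-visit), semi-structured EHR smoking fields (coded status drop-downs
and pack-year entries), and an external questionnaire used as the reference
standard. All three travel as either comma-delimited files with a header or
JSON-lines; column names are remappable because real EHR exports rarely
agree on them.

Readers never silently drop rows: every input row becomes either a parsed
record or a :class:`RowError` carrying the row index, and
``len(records) + len(errors)`` always equals the input row count. A missing
required column raises :class:`SchemaError` up front. Dates are emitted as
ISO-8601; absent optionals serialize as the empty string (CSV) or ``null``
(JSON-lines).
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .status import SmokingStatus

_DATE_FORMATS = ("%Y-%m-%d", "%m/%d/%Y", "%m/%d/%y")


class SchemaError(ValueError):
    """A required column is absent from the input file."""


@dataclass(frozen=True)
class RowError:
    row_index: int
    message: str


@dataclass
class ReadResult:
    records: list
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ClinicalNote:
    """One patient-visit free-text note — the unit of classification."""

    note_id: str
    patient_id: str
    note_date: dt.date
    text: str


@dataclass(frozen=True)
class SemiStructuredRecord:
    """A coded EHR smoking entry recorded on a visit date."""

    patient_id: str
    record_date: dt.date
    status: Optional[SmokingStatus] = None
    pack_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pack_years is not None and self.pack_years < 0:
            raise ValueError("pack_years must be non-negative")


@dataclass(frozen=True)
class QuestionnaireRecord:
    """External questionnaire response: status plus self-reported history.

    ``declined`` marks smokers who declined the packs-per-day / years-smoked
    questions; never-smokers carry no pack-year fields at all.
    """

    patient_id: str
    status: Optional[SmokingStatus] = None
    packs_per_day: Optional[float] = None
    years_smoked: Optional[float] = None
    declined: bool = False

    @property
    def pack_years(self) -> Optional[float]:
        if self.packs_per_day is None or self.years_smoked is None:
            return None
        return self.packs_per_day * self.years_smoked


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the canonical field names to the file's column names."""

    note_id: str = "note_id"
    patient_id: str = "patient_id"
    note_date: str = "note_date"
    text: str = "text"
    record_date: str = "record_date"
    status: str = "status"
    pack_years: str = "pack_years"
    packs_per_day: str = "packs_per_day"
    years_smoked: str = "years_smoked"


def parse_date(value: str) -> dt.date:
    value = value.strip()
    for fmt in _DATE_FORMATS:
        try:
            return dt.datetime.strptime(value, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {value!r}")


def _is_jsonl(path: Path) -> bool:
    return path.suffix.lower() in (".jsonl", ".ndjson", ".json")


def _iter_rows(path: Path) -> tuple[list[str], list[dict]]:
    """Return (available column names, list of row dicts) for either dialect."""
    path = Path(path)
    if _is_jsonl(path):
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        cols = sorted({k for r in rows for k in r})
        return cols, rows
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = list(reader.fieldnames or [])
        return cols, list(reader)


def _require(cols: Sequence[str], names: Iterable[str], rows: list[dict]) -> None:
    # JSON-lines files may legitimately omit optional keys; only required
    # names are enforced, and an empty file passes (nothing to violate).
    if not rows and not cols:
        return
    for name in names:
        if name not in cols:
            raise SchemaError(f"missing required column: {name!r}")


def _get(row: dict, col: str):
    v = row.get(col)
    if v is None:
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    return v


def read_notes(path, columns: ColumnMap = ColumnMap()) -> ReadResult:
    """Read clinical notes from CSV or JSON-lines; row order preserved."""
    cols, rows = _iter_rows(Path(path))
    _require(cols, (columns.note_id, columns.patient_id, columns.note_date), rows)
    result = ReadResult([])
    for i, row in enumerate(rows):
        try:
            date_raw = _get(row, columns.note_date)
            if date_raw is None:
                raise ValueError("missing note date")
            result.records.append(
                ClinicalNote(
                    note_id=str(_get(row, columns.note_id)),
                    patient_id=str(_get(row, columns.patient_id)),
                    note_date=parse_date(str(date_raw)),
                    text=str(_get(row, columns.text) or ""),
                )
            )
        except (ValueError, TypeError) as exc:
            result.errors.append(RowError(i, str(exc)))
    return result


def read_semistructured(path, columns: ColumnMap = ColumnMap()) -> ReadResult:
    cols, rows = _iter_rows(Path(path))
    _require(cols, (columns.patient_id, columns.record_date), rows)
    result = ReadResult([])
    for i, row in enumerate(rows):
        try:
            status_raw = _get(row, columns.status)
            py_raw = _get(row, columns.pack_years)
            date_raw = _get(row, columns.record_date)
            if date_raw is None:
                raise ValueError("missing record date")
            result.records.append(
                SemiStructuredRecord(
                    patient_id=str(_get(row, columns.patient_id)),
                    record_date=parse_date(str(date_raw)),
                    status=None if status_raw is None else SmokingStatus.from_string(str(status_raw)),
                    pack_years=None if py_raw is None else float(py_raw),
                )
            )
        except (ValueError, TypeError) as exc:
            result.errors.append(RowError(i, str(exc)))
    return result


def read_questionnaire(path, columns: ColumnMap = ColumnMap()) -> ReadResult:
    cols, rows = _iter_rows(Path(path))
    _require(cols, (columns.patient_id,), rows)
    result = ReadResult([])
    for i, row in enumerate(rows):
        try:
            status_raw = _get(row, columns.status)
            declined = False
            status: Optional[SmokingStatus] = None
            if status_raw is not None:
                if str(status_raw).strip().lower() == "declined":
                    declined = True
                else:
                    status = SmokingStatus.from_string(str(status_raw))
            ppd = _get(row, columns.packs_per_day)
            yrs = _get(row, columns.years_smoked)
            declined_q = _get(row, "declined")
            if declined_q is not None:
                declined = str(declined_q).strip().lower() in ("1", "true", "yes")
            result.records.append(
                QuestionnaireRecord(
                    patient_id=str(_get(row, columns.patient_id)),
                    status=status,
                    packs_per_day=None if ppd is None else float(ppd),
                    years_smoked=None if yrs is None else float(yrs),
                    declined=declined,
                )
            )
        except (ValueError, TypeError) as exc:
            result.errors.append(RowError(i, str(exc)))
    return result


# ---------------------------------------------------------------------------
# Registry output


_REGISTRY_COLUMNS = (
    "patient_id",
    "status_nlp",
    "status_semi",
    "status_merged",
    "pack_years_nlp",
    "pack_years_semi",
    "pack_years_merged",
    "cessation_date",
    "note_source",
    "semi_source",
)


def write_registry(profiles: Sequence, path) -> int:
    """Write merged :class:`~smokereg.merge.SmokingProfile` rows; returns count."""
    path = Path(path)
    rows = [_profile_to_row(p) for p in profiles]
    if _is_jsonl(path):
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REGISTRY_COLUMNS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    return len(rows)


def read_registry(path) -> ReadResult:
    from .merge import SmokingProfile  # local import; merge depends on io types

    cols, rows = _iter_rows(Path(path))
    _require(cols, ("patient_id", "status_nlp", "status_merged"), rows)
    result = ReadResult([])
    for i, row in enumerate(rows):
        try:
            result.records.append(_row_to_profile(row, SmokingProfile))
        except (ValueError, TypeError) as exc:
            result.errors.append(RowError(i, str(exc)))
    return result


def _profile_to_row(p) -> dict:
    return {
        "patient_id": p.patient_id,
        "status_nlp": str(p.status_nlp),
        "status_semi": None if p.status_semi is None else str(p.status_semi),
        "status_merged": str(p.status_merged),
        "pack_years_nlp": p.pack_years_nlp,
        "pack_years_semi": p.pack_years_semi,
        "pack_years_merged": p.pack_years_merged,
        "cessation_date": None if p.cessation_date is None else p.cessation_date.isoformat(),
        "note_source": int(p.note_source),
        "semi_source": int(p.semi_source),
    }


def _row_to_profile(row: dict, cls):
    def opt_float(v):
        return None if v is None else float(v)

    def opt_status(v):
        return None if v is None else SmokingStatus.from_string(str(v))

    g = lambda k: _get(row, k)
    return cls(
        patient_id=str(g("patient_id")),
        status_nlp=SmokingStatus.from_string(str(g("status_nlp"))),
        status_semi=opt_status(g("status_semi")),
        pack_years_nlp=opt_float(g("pack_years_nlp")),
        pack_years_semi=opt_float(g("pack_years_semi")),
        cessation_date=None if g("cessation_date") is None else parse_date(str(g("cessation_date"))),
        note_source=bool(int(g("note_source") or 0)),
        semi_source=bool(int(g("semi_source") or 0)),
    )


# Generic writers used by the simulator's CLI path -------------------------


def write_notes(notes: Sequence[ClinicalNote], path) -> int:
    return _write_records(
        path,
        ("note_id", "patient_id", "note_date", "text"),
        [
            {
                "note_id": n.note_id,
                "patient_id": n.patient_id,
                "note_date": n.note_date.isoformat(),
                "text": n.text,
            }
            for n in notes
        ],
    )


def write_semistructured(records: Sequence[SemiStructuredRecord], path) -> int:
    return _write_records(
        path,
        ("patient_id", "record_date", "status", "pack_years"),
        [
            {
                "patient_id": r.patient_id,
                "record_date": r.record_date.isoformat(),
                "status": None if r.status is None else str(r.status),
                "pack_years": r.pack_years,
            }
            for r in records
        ],
    )


def write_questionnaire(records: Sequence[QuestionnaireRecord], path) -> int:
    return _write_records(
        path,
        ("patient_id", "status", "packs_per_day", "years_smoked", "declined"),
        [
            {
                "patient_id": r.patient_id,
                "status": None if r.status is None else str(r.status),
                "packs_per_day": r.packs_per_day,
                "years_smoked": r.years_smoked,
                "declined": int(r.declined),
            }
            for r in records
        ],
    )


def _write_records(path, columns: tuple[str, ...], rows: list[dict]) -> int:
    path = Path(path)
    if _is_jsonl(path):
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    return len(rows)
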