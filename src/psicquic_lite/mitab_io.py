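"""Streaming reader/writer for PSI-MITAB 2.5 / 2.6 / 2.7.

The three dialects are strict column-prefix extensions of one another:
2.5 carries 15 columns, 2.6 appends 21 (36 total), 2.7 appends a further
6 (42 total).  The absolute column order is fixed once, in :data:`COLUMNS`,
so a correction touches a single table.

Reading is line-streaming (constant memory in file length); a single
optional leading ``#`` header line is tolerated and never written by
default; blank lines are skipped.  Files are treated as UTF-8 text.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _field
from typing import Callable, IO, Iterable, Iterator, List, Optional, Tuple

from .mitab_model import (
    EMPTY_COLUMN, InteractionEvidence, MitabValueError, Organism,
    format_values, parse_values, validate_record,
)
from . import mitab_model as _model

__all__ = [
    "Dialect", "DIALECTS", "ParseIssue", "MitabParseError", "DialectLossError",
    "UnrecognizedDialectError", "detect_dialect", "read_records",
    "write_records", "convert", "render_line",
]


class MitabParseError(ValueError):
    def __init__(self, message: str, line_number: int = 0):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}" if line_number else message)


class UnrecognizedDialectError(MitabParseError):
    pass


class DialectLossError(ValueError):
    """Raised when a lossless write would drop populated fields."""

    def __init__(self, fields: List[str], dialect: str):
        self.fields = fields
        super().__init__(
            f"record carries fields outside MITAB {dialect}: {', '.join(fields)}")


@dataclass(frozen=True)
class ParseIssue:
    line_number: int
    message: str


# ---------------------------------------------------------------------------
# Column table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Column:
    name: str
    read: Callable[[InteractionEvidence, str], None]
    write: Callable[[InteractionEvidence], str]


def _list_col(name: str, kind: str, get: Callable[[InteractionEvidence], list]) -> _Column:
    def read(rec, raw):
        get(rec).extend(parse_values(raw, kind, column=name))

    def write(rec):
        return format_values(get(rec))

    return _Column(name, read, write)


def _text_list_col(name: str, get: Callable[[InteractionEvidence], list]) -> _Column:
    # free-text columns (first author): "|"-separated, no value grammar
    def read(rec, raw):
        raw = raw.strip()
        if raw not in ("", EMPTY_COLUMN):
            get(rec).extend(raw.split("|"))

    def write(rec):
        values = get(rec)
        return "|".join(values) if values else EMPTY_COLUMN

    return _Column(name, read, write)


def _organism_col(name: str, get, put) -> _Column:
    def read(rec, raw):
        values = parse_values(raw, "organism", column=name)
        if values:
            put(rec, values[0])

    def write(rec):
        org = get(rec)
        return format_values([org] if org is not None else [])

    return _Column(name, read, write)


def _term_single_col(name: str, get, put) -> _Column:
    def read(rec, raw):
        values = parse_values(raw, "term", column=name)
        if values:
            put(rec, values[0])

    def write(rec):
        term = get(rec)
        return format_values([term] if term is not None else [])

    return _Column(name, read, write)


_DATE_FORMAT = "%Y/%m/%d"


def _date_col(name: str, get, put) -> _Column:
    def read(rec, raw):
        raw = raw.strip()
        if raw in ("", EMPTY_COLUMN):
            return
        try:
            put(rec, _dt.datetime.strptime(raw, _DATE_FORMAT).date())
        except ValueError:
            raise MitabValueError("invalid date (expected yyyy/mm/dd)", raw, name)

    def write(rec):
        date = get(rec)
        return date.strftime(_DATE_FORMAT) if date is not None else EMPTY_COLUMN

    return _Column(name, read, write)


def _bool_col(name: str, get, put) -> _Column:
    def read(rec, raw):
        raw = raw.strip().lower()
        if raw in ("", EMPTY_COLUMN, "false"):
            put(rec, False)
        elif raw == "true":
            put(rec, True)
        else:
            raise MitabValueError("expected true/false", raw, name)

    def write(rec):
        return "true" if get(rec) else "false"

    return _Column(name, read, write)


def _int_col(name: str, get, put) -> _Column:
    def read(rec, raw):
        raw = raw.strip()
        if raw in ("", EMPTY_COLUMN):
            return
        try:
            put(rec, int(raw))
        except ValueError:
            raise MitabValueError("expected an integer", raw, name)

    def write(rec):
        value = get(rec)
        return str(value) if value is not None else EMPTY_COLUMN

    return _Column(name, read, write)


def _a(rec):
    return rec.participant_a


def _b(rec):
    return rec.participant_b


#: Absolute MITAB column order; 2.5 = first 15, 2.6 = first 36, 2.7 = all 42.
COLUMNS: Tuple[_Column, ...] = (
    _list_col("ID(s) interactor A", "xref", lambda r: _a(r).primary_ids),
    _list_col("ID(s) interactor B", "xref", lambda r: _b(r).primary_ids),
    _list_col("Alt. ID(s) interactor A", "xref", lambda r: _a(r).alt_ids),
    _list_col("Alt. ID(s) interactor B", "xref", lambda r: _b(r).alt_ids),
    _list_col("Alias(es) interactor A", "alias", lambda r: _a(r).aliases),
    _list_col("Alias(es) interactor B", "alias", lambda r: _b(r).aliases),
    _list_col("Interaction detection method(s)", "term", lambda r: r.detection_methods),
    _text_list_col("Publication 1st author(s)", lambda r: r.first_authors),
    _list_col("Publication Identifier(s)", "xref", lambda r: r.publication_ids),
    _organism_col("Taxid interactor A", lambda r: _a(r).taxid,
                  lambda r, v: setattr(_a(r), "taxid", v)),
    _organism_col("Taxid interactor B", lambda r: _b(r).taxid,
                  lambda r, v: setattr(_b(r), "taxid", v)),
    _list_col("Interaction type(s)", "term", lambda r: r.interaction_types),
    _list_col("Source database(s)", "term", lambda r: r.source_databases),
    _list_col("Interaction identifier(s)", "xref", lambda r: r.interaction_ids),
    _list_col("Confidence value(s)", "confidence", lambda r: r.confidences),
    # --- MITAB 2.6 additions ---
    _term_single_col("Expansion method(s)", lambda r: r.expansion_method,
                     lambda r, v: setattr(r, "expansion_method", v)),
    _list_col("Biological role(s) interactor A", "term", lambda r: _a(r).biological_role),
    _list_col("Biological role(s) interactor B", "term", lambda r: _b(r).biological_role),
    _list_col("Experimental role(s) interactor A", "term", lambda r: _a(r).experimental_role),
    _list_col("Experimental role(s) interactor B", "term", lambda r: _b(r).experimental_role),
    _list_col("Type(s) interactor A", "term", lambda r: _a(r).interactor_type),
    _list_col("Type(s) interactor B", "term", lambda r: _b(r).interactor_type),
    _list_col("Xref(s) interactor A", "xref", lambda r: _a(r).xrefs),
    _list_col("Xref(s) interactor B", "xref", lambda r: _b(r).xrefs),
    _list_col("Interaction Xref(s)", "xref", lambda r: r.interaction_xrefs),
    _list_col("Annotation(s) interactor A", "annotation", lambda r: _a(r).annotations),
    _list_col("Annotation(s) interactor B", "annotation", lambda r: _b(r).annotations),
    _list_col("Interaction annotation(s)", "annotation", lambda r: r.interaction_annotations),
    _organism_col("Host organism(s)", lambda r: r.host_organism,
                  lambda r, v: setattr(r, "host_organism", v)),
    _list_col("Interaction parameter(s)", "parameter", lambda r: r.parameters),
    _date_col("Creation date", lambda r: r.creation_date,
              lambda r, v: setattr(r, "creation_date", v)),
    _date_col("Update date", lambda r: r.update_date,
              lambda r, v: setattr(r, "update_date", v)),
    _list_col("Checksum(s) interactor A", "checksum", lambda r: _a(r).checksums),
    _list_col("Checksum(s) interactor B", "checksum", lambda r: _b(r).checksums),
    _list_col("Interaction Checksum(s)", "checksum", lambda r: r.interaction_checksums),
    _bool_col("Negative", lambda r: r.negative,
              lambda r, v: setattr(r, "negative", v)),
    # --- MITAB 2.7 additions ---
    _list_col("Feature(s) interactor A", "feature", lambda r: _a(r).features),
    _list_col("Feature(s) interactor B", "feature", lambda r: _b(r).features),
    _int_col("Stoichiometry(s) interactor A", lambda r: _a(r).stoichiometry,
             lambda r, v: setattr(_a(r), "stoichiometry", v)),
    _int_col("Stoichiometry(s) interactor B", lambda r: _b(r).stoichiometry,
             lambda r, v: setattr(_b(r), "stoichiometry", v)),
    _list_col("Identification method participant A", "term",
              lambda r: _a(r).participant_detection_methods),
    _list_col("Identification method participant B", "term",
              lambda r: _b(r).participant_detection_methods),
)


@dataclass(frozen=True)
class Dialect:
    """One MITAB format version and its column layout."""

    version: str
    column_count: int

    @property
    def columns(self) -> Tuple[_Column, ...]:
        return COLUMNS[: self.column_count]

    @property
    def column_order(self) -> Tuple[str, ...]:
        return tuple(c.name for c in self.columns)


DIALECTS = {
    "2.5": Dialect("2.5", 15),
    "2.6": Dialect("2.6", 36),
    "2.7": Dialect("2.7", 42),
}
_BY_COUNT = {d.column_count: d for d in DIALECTS.values()}


def _as_dialect(dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[str(dialect)]
    except KeyError:
        raise ValueError(f"unknown MITAB dialect {dialect!r}") from None


def detect_dialect(line: str) -> Dialect:
    """Identify the dialect of one data line by its tab-separated field count."""
    count = len(line.rstrip("\n").split("\t"))
    try:
        return _BY_COUNT[count]
    except KeyError:
        raise UnrecognizedDialectError(
            f"line has {count} columns; expected 15 (2.5), 36 (2.6) or 42 (2.7)"
        ) from None


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def parse_line(line: str, dialect: Dialect, line_number: int = 0) -> InteractionEvidence:
    """Parse one tab-delimited data line into a record."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != dialect.column_count:
        raise MitabParseError(
            f"expected {dialect.column_count} columns, found {len(fields)}",
            line_number)
    record = InteractionEvidence()
    for column, raw in zip(dialect.columns, fields):
        try:
            column.read(record, raw)
        except MitabValueError as exc:
            raise MitabParseError(str(exc), line_number) from exc
    return record


def read_records(stream: Iterable[str], dialect=None, *, strict: bool = False,
                 issues: Optional[List[ParseIssue]] = None,
                 ) -> Iterator[InteractionEvidence]:
    """Lazily parse records from an iterable of lines.

    The dialect is detected from the first data line when not given.  In
    non-strict mode per-line failures are appended to *issues* (when
    supplied) and the line is skipped; in strict mode the first failure
    raises :class:`MitabParseError` with its line number.
    """
    if dialect is not None:
        dialect = _as_dialect(dialect)
    for line_number, line in enumerate(stream, start=1):
        stripped = line.rstrip("\n")
        if line_number == 1 and stripped.startswith("#"):
            continue
        if not stripped.strip():
            if issues is not None:
                issues.append(ParseIssue(line_number, "blank line skipped"))
            continue
        try:
            if dialect is None:
                dialect = detect_dialect(stripped)
            yield parse_line(stripped, dialect, line_number)
        except (MitabParseError, MitabValueError) as exc:
            if strict:
                if isinstance(exc, MitabParseError):
                    raise
                raise MitabParseError(str(exc), line_number) from exc
            if issues is not None:
                issues.append(ParseIssue(line_number, str(exc)))


def read_file(path, dialect=None, **kwargs) -> List[InteractionEvidence]:
    """Eagerly read a MITAB file from *path*."""
    with open(path, encoding="utf-8") as handle:
        return list(read_records(handle, dialect, **kwargs))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _out_of_dialect_fields(record: InteractionEvidence, dialect: Dialect) -> List[str]:
    gated = []
    if dialect.version == "2.5":
        gated = _model._FIELDS_26 + _model._FIELDS_27
    elif dialect.version == "2.6":
        gated = _model._FIELDS_27
    return [name for name, populated in gated if populated(record)]


def render_line(record: InteractionEvidence, dialect, *, lossy: bool = False) -> str:
    """Serialize one record to a tab-delimited line of the dialect's width."""
    dialect = _as_dialect(dialect)
    if not lossy:
        dropped = _out_of_dialect_fields(record, dialect)
        if dropped:
            raise DialectLossError(dropped, dialect.version)
    return "\t".join(column.write(record) for column in dialect.columns)


def write_records(records: Iterable[InteractionEvidence], dialect, stream: IO[str],
                  *, lossy: bool = False) -> int:
    """Write records as MITAB lines; returns the number of lines written."""
    dialect = _as_dialect(dialect)
    count = 0
    for record in records:
        stream.write(render_line(record, dialect, lossy=lossy))
        stream.write("\n")
        count += 1
    return count


def write_file(records: Iterable[InteractionEvidence], dialect, path,
               *, lossy: bool = False) -> int:
    with open(path, "w", encoding="utf-8") as handle:
        return write_records(records, dialect, handle, lossy=lossy)


def convert(in_stream: Iterable[str], out_stream: IO[str], target, *,
            lossy: bool = False, strict: bool = True) -> dict:
    """Re-serialize a MITAB stream at the *target* dialect.

    Upgrading pads the new columns with "-"; downgrading drops populated
    out-of-prefix fields only when ``lossy=True``, otherwise it raises
    :class:`DialectLossError`.  Returns ``{"records": n, "fields_dropped": k}``.
    """
    target = _as_dialect(target)
    records = 0
    fields_dropped = 0
    for record in read_records(in_stream, strict=strict):
        dropped = _out_of_dialect_fields(record, target)
        if dropped and not lossy:
            raise DialectLossError(dropped, target.version)
        fields_dropped += len(dropped)
        out_stream.write(render_line(record, target, lossy=True))
        out_stream.write("\n")
        records += 1
    return {"records": records, "fields_dropped": fields_dropped}
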