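"""Domain model for PSI-MITAB interaction records.

A MITAB file describes one binary interaction evidence per tab-delimited
line.  Each column holds zero or more values separated by ``|``; the single
character ``-`` denotes an empty column.  Most values follow the
``database:identifier(free text)`` shape, where any component containing a
reserved character is wrapped in double quotes with backslash-escaped
embedded quotes (the de-facto MITAB 2.6+ convention).

This module defines the typed values, the two participants, the record
itself, the column value parser/formatter, and record-level validation
against the three dialects (2.5 / 2.6 / 2.7).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

__all__ = [
    "ControlledTerm", "CrossReference", "Alias", "Confidence", "Annotation",
    "Parameter", "Checksum", "Feature", "Organism", "Participant",
    "InteractionEvidence", "MitabValueError", "parse_values", "format_values",
    "validate_record", "EMPTY_COLUMN",
]

#: Sentinel written for an empty column.
EMPTY_COLUMN = "-"


class MitabValueError(ValueError):
    """Raised for a malformed column value; carries the offending segment."""

    def __init__(self, message: str, segment: str = "", column: str = ""):
        self.segment = segment
        self.column = column
        prefix = f"[{column}] " if column else ""
        suffix = f" in segment {segment!r}" if segment else ""
        super().__init__(f"{prefix}{message}{suffix}")


# ---------------------------------------------------------------------------
# Typed column values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlledTerm:
    """A vocabulary-anchored value, e.g. ``psi-mi:"MI:0407"(direct interaction)``."""

    database: str
    identifier: str
    label: str = ""


@dataclass(frozen=True)
class CrossReference:
    database: str
    identifier: str
    qualifier: str = ""


@dataclass(frozen=True)
class Alias:
    database: str
    name: str
    alias_type: str = ""


@dataclass(frozen=True)
class Confidence:
    score_type: str
    value: str = ""


@dataclass(frozen=True)
class Annotation:
    topic: str
    text: str = ""


@dataclass(frozen=True)
class Parameter:
    parameter_type: str
    value: str
    text: str = ""


@dataclass(frozen=True)
class Checksum:
    method: str
    value: str


@dataclass(frozen=True)
class Feature:
    """A sequence feature; ranges are opaque verbatim strings ("1-10", "?-?")."""

    feature_type: str
    ranges: tuple
    text: str = ""

    def __post_init__(self):
        object.__setattr__(self, "ranges", tuple(self.ranges))
        if not self.ranges:
            raise MitabValueError("feature requires at least one range")


@dataclass(frozen=True)
class Organism:
    """NCBI taxon; negative sentinel taxids (-1 "in vitro", -2 ...) permitted."""

    taxid: int
    name: str = ""


TypedValue = Union[ControlledTerm, CrossReference, Alias, Confidence,
                   Annotation, Parameter, Checksum, Feature, Organism]


# ---------------------------------------------------------------------------
# Participants and records
# ---------------------------------------------------------------------------

@dataclass
class Participant:
    """One interactor's slice of a MITAB line (identifier, taxon, roles...)."""

    primary_ids: List[CrossReference] = field(default_factory=list)
    alt_ids: List[CrossReference] = field(default_factory=list)
    aliases: List[Alias] = field(default_factory=list)
    taxid: Optional[Organism] = None
    biological_role: List[ControlledTerm] = field(default_factory=list)
    experimental_role: List[ControlledTerm] = field(default_factory=list)
    interactor_type: List[ControlledTerm] = field(default_factory=list)
    xrefs: List[CrossReference] = field(default_factory=list)
    annotations: List[Annotation] = field(default_factory=list)
    checksums: List[Checksum] = field(default_factory=list)
    features: List[Feature] = field(default_factory=list)
    stoichiometry: Optional[int] = None
    participant_detection_methods: List[ControlledTerm] = field(default_factory=list)

    def is_empty(self) -> bool:
        """True when every field is unset — the empty B side of an
        intra-molecular interaction."""
        return not any((
            self.primary_ids, self.alt_ids, self.aliases, self.taxid,
            self.biological_role, self.experimental_role, self.interactor_type,
            self.xrefs, self.annotations, self.checksums, self.features,
            self.stoichiometry is not None, self.participant_detection_methods,
        ))


@dataclass
class InteractionEvidence:
    """One binary interaction evidence — a full MITAB record.

    ``expansion_method`` set means the pair was derived from an n-ary
    interaction by spoke/matrix/bipartite expansion, not observed as binary.
    ``negative`` flags evidence that the interaction does NOT occur.
    """

    participant_a: Participant = field(default_factory=Participant)
    participant_b: Participant = field(default_factory=Participant)
    detection_methods: List[ControlledTerm] = field(default_factory=list)
    first_authors: List[str] = field(default_factory=list)
    publication_ids: List[CrossReference] = field(default_factory=list)
    interaction_types: List[ControlledTerm] = field(default_factory=list)
    source_databases: List[ControlledTerm] = field(default_factory=list)
    interaction_ids: List[CrossReference] = field(default_factory=list)
    confidences: List[Confidence] = field(default_factory=list)
    expansion_method: Optional[ControlledTerm] = None
    interaction_xrefs: List[CrossReference] = field(default_factory=list)
    interaction_annotations: List[Annotation] = field(default_factory=list)
    host_organism: Optional[Organism] = None
    parameters: List[Parameter] = field(default_factory=list)
    creation_date: Optional[_dt.date] = None
    update_date: Optional[_dt.date] = None
    interaction_checksums: List[Checksum] = field(default_factory=list)
    negative: bool = False


# ---------------------------------------------------------------------------
# Column value grammar
# ---------------------------------------------------------------------------

# Characters that force quoting of an atom anywhere in a column value.
_RESERVED = set('|():"\t\n')


def _escape(atom: str, extra: str = "") -> str:
    """Quote *atom* when it contains a reserved character (or an *extra*
    context-reserved one such as "," inside feature ranges), is empty, or
    would collide with the "-" empty-column sentinel."""
    if (atom == "" or atom == EMPTY_COLUMN or atom != atom.strip()
            or any(c in _RESERVED or c in extra for c in atom)):
        quoted = atom.replace("\\", "\\\\").replace('"', '\\"')
        # tab/newline would break the tab-delimited line even inside quotes
        quoted = (quoted.replace("\t", "\\t").replace("\n", "\\n")
                  .replace("\r", "\\r"))
        return '"' + quoted + '"'
    return atom


# A scanned value is a list of colon-separated *parts*; each part is a list
# of (text, was_quoted) segments, plus an optional trailing "(...)" group.

def _split_top(raw: str, sep: str) -> List[str]:
    """Split on *sep* outside double quotes (backslash escapes inside)."""
    out, buf, in_q, i = [], [], False, 0
    while i < len(raw):
        c = raw[i]
        if in_q:
            if c == "\\" and i + 1 < len(raw):
                buf.append(c)
                buf.append(raw[i + 1])
                i += 2
                continue
            if c == '"':
                in_q = False
            buf.append(c)
        elif c == '"':
            in_q = True
            buf.append(c)
        elif c == sep:
            out.append("".join(buf))
            buf = []
        else:
            buf.append(c)
        i += 1
    if in_q:
        raise MitabValueError("unbalanced quote", raw)
    out.append("".join(buf))
    return out


def _scan_value(raw: str):
    """Scan one "|"-separated value into (parts, paren_text, has_paren)."""
    parts: List[List[tuple]] = [[]]
    paren: Optional[str] = None
    i, n = 0, len(raw)
    while i < n:
        c = raw[i]
        if c == '"':
            seg, i = _read_quoted(raw, i)
            parts[-1].append((seg, True))
        elif c == ":":
            parts.append([])
            i += 1
        elif c == "(":
            paren, i = _read_paren(raw, i)
            if i != n:
                raise MitabValueError("text after closing parenthesis", raw)
        elif c == ")":
            raise MitabValueError("unbalanced parenthesis", raw)
        else:
            j = i
            while j < n and raw[j] not in ':("':
                if raw[j] == ")":
                    raise MitabValueError("unbalanced parenthesis", raw)
                j += 1
            parts[-1].append((raw[i:j], False))
            i = j
    return parts, paren


def _read_quoted(raw: str, i: int):
    """Read a double-quoted segment starting at raw[i] == '"'; unescape."""
    buf = []
    i += 1
    escapes = {"t": "\t", "n": "\n", "r": "\r"}
    while i < len(raw):
        c = raw[i]
        if c == "\\" and i + 1 < len(raw):
            nxt = raw[i + 1]
            buf.append(escapes.get(nxt, nxt))
            i += 2
            continue
        if c == '"':
            return "".join(buf), i + 1
        buf.append(c)
        i += 1
    raise MitabValueError("unbalanced quote", raw)


def _read_paren(raw: str, i: int):
    """Read a trailing "(...)" group starting at raw[i] == '('."""
    i += 1
    if i < len(raw) and raw[i] == '"':
        text, i = _read_quoted(raw, i)
        if i >= len(raw) or raw[i] != ")":
            raise MitabValueError("unbalanced parenthesis", raw)
        return text, i + 1
    j = raw.find(")", i)
    if j < 0:
        raise MitabValueError("unbalanced parenthesis", raw)
    return raw[i:j], j + 1


def _flat(part: Sequence[tuple]) -> str:
    return "".join(seg for seg, _ in part)


def _join_tail(parts) -> str:
    """Rejoin parts[1:] with ":" — tolerates unquoted identifiers that
    themselves contain colons (e.g. bare MI:0407)."""
    return ":".join(_flat(p) for p in parts[1:])


def _split_ranges(part) -> List[str]:
    """Split a feature-range part on commas in unquoted segments only."""
    ranges, buf = [], []
    for seg, quoted in part:
        if quoted:
            buf.append(seg)
            continue
        pieces = seg.split(",")
        buf.append(pieces[0])
        for piece in pieces[1:]:
            ranges.append("".join(buf))
            buf = [piece]
    ranges.append("".join(buf))
    return ranges


_KINDS = ("xref", "term", "alias", "confidence", "annotation", "parameter",
          "checksum", "feature", "organism")


def parse_values(raw: str, kind: str, column: str = "") -> List[TypedValue]:
    """Parse one column's text into a list of typed values.

    ``kind`` selects the target type: one of xref, term, alias, confidence,
    annotation, parameter, checksum, feature, organism.  The sentinel "-"
    yields the empty list.  Malformed segments raise :class:`MitabValueError`
    naming the column and segment.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown value kind: {kind!r}")
    raw = raw.strip()
    if raw == EMPTY_COLUMN or raw == "":
        return []
    values: List[TypedValue] = []
    for segment in _split_top(raw, "|"):
        try:
            values.append(_parse_one(segment, kind))
        except MitabValueError as exc:
            raise MitabValueError(str(exc.args[0]).split(" in segment")[0],
                                  segment, column) from exc
    return values


def _require(cond: bool, msg: str, segment: str):
    if not cond:
        raise MitabValueError(msg, segment)


def _parse_one(segment: str, kind: str) -> TypedValue:
    parts, paren = _scan_value(segment)
    head = _flat(parts[0])
    tail = _join_tail(parts)
    two = len(parts) >= 2
    if kind == "xref":
        _require(two and head and tail, 'expected "db:id" cross-reference', segment)
        return CrossReference(head, tail, paren or "")
    if kind == "term":
        _require(two and head and tail, 'expected "db:accession" controlled term', segment)
        return ControlledTerm(head, tail, paren or "")
    if kind == "alias":
        _require(two and head and tail, 'expected "db:name" alias', segment)
        return Alias(head, tail, paren or "")
    if kind == "confidence":
        _require(bool(head), "missing confidence score type", segment)
        _require(paren is None, "unexpected parenthesized text", segment)
        return Confidence(head, tail if two else "")
    if kind == "annotation":
        _require(bool(head), "missing annotation topic", segment)
        _require(paren is None, "unexpected parenthesized text", segment)
        return Annotation(head, tail if two else "")
    if kind == "parameter":
        _require(two and head, 'expected "type:value" parameter', segment)
        return Parameter(head, tail, paren or "")
    if kind == "checksum":
        _require(two and head and tail, 'expected "method:value" checksum', segment)
        return Checksum(head, tail)
    if kind == "feature":
        _require(two and head, 'expected "type:range[,range]" feature', segment)
        ranges = _split_ranges(parts[1])
        extra = [_flat(p) for p in parts[2:]]
        if extra:  # unquoted range text containing ":" — keep it verbatim
            ranges[-1] = ":".join([ranges[-1], *extra])
        _require(all(ranges), "empty feature range", segment)
        return Feature(head, tuple(ranges), paren or "")
    if kind == "organism":
        taxid_text = tail if two else head
        try:
            taxid = int(taxid_text)
        except ValueError:
            raise MitabValueError("taxid is not an integer", segment)
        return Organism(taxid, paren or "")
    raise AssertionError(kind)


def format_values(values: Iterable[TypedValue]) -> str:
    """Serialize typed values to column text; the inverse of
    :func:`parse_values` (``parse_values(format_values(v)) == v``)."""
    rendered = [_format_one(v) for v in values]
    return "|".join(rendered) if rendered else EMPTY_COLUMN


def _paren(text: str) -> str:
    return f"({_escape(text)})" if text else ""


def _format_one(v: TypedValue) -> str:
    if isinstance(v, ControlledTerm):
        return f"{_escape(v.database)}:{_escape(v.identifier)}{_paren(v.label)}"
    if isinstance(v, CrossReference):
        return f"{_escape(v.database)}:{_escape(v.identifier)}{_paren(v.qualifier)}"
    if isinstance(v, Alias):
        return f"{_escape(v.database)}:{_escape(v.name)}{_paren(v.alias_type)}"
    if isinstance(v, Confidence):
        if v.value == "":
            return _escape(v.score_type)
        return f"{_escape(v.score_type)}:{_escape(v.value)}"
    if isinstance(v, Annotation):
        if v.text == "":
            return _escape(v.topic)
        return f"{_escape(v.topic)}:{_escape(v.text)}"
    if isinstance(v, Parameter):
        return f"{_escape(v.parameter_type)}:{_escape(v.value)}{_paren(v.text)}"
    if isinstance(v, Checksum):
        return f"{_escape(v.method)}:{_escape(v.value)}"
    if isinstance(v, Feature):
        ranges = ",".join(_escape(r, extra=",") for r in v.ranges)
        return f"{_escape(v.feature_type)}:{ranges}{_paren(v.text)}"
    if isinstance(v, Organism):
        return f"taxid:{v.taxid}{_paren(v.name)}"
    raise TypeError(f"cannot serialize {type(v).__name__}")


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------

# Fields introduced after 2.5, as (human name, predicate over the record).
_FIELDS_26 = [
    ("expansion method", lambda r: r.expansion_method is not None),
    ("biological role", lambda r: r.participant_a.biological_role or r.participant_b.biological_role),
    ("experimental role", lambda r: r.participant_a.experimental_role or r.participant_b.experimental_role),
    ("interactor type", lambda r: r.participant_a.interactor_type or r.participant_b.interactor_type),
    ("participant xref", lambda r: r.participant_a.xrefs or r.participant_b.xrefs),
    ("interaction xref", lambda r: r.interaction_xrefs),
    ("participant annotation", lambda r: r.participant_a.annotations or r.participant_b.annotations),
    ("interaction annotation", lambda r: r.interaction_annotations),
    ("host organism", lambda r: r.host_organism is not None),
    ("parameter", lambda r: r.parameters),
    ("creation date", lambda r: r.creation_date is not None),
    ("update date", lambda r: r.update_date is not None),
    ("checksum", lambda r: (r.participant_a.checksums or r.participant_b.checksums
                            or r.interaction_checksums)),
    ("negative flag", lambda r: r.negative),
]

_FIELDS_27 = [
    ("feature", lambda r: r.participant_a.features or r.participant_b.features),
    ("stoichiometry", lambda r: (r.participant_a.stoichiometry is not None
                                 or r.participant_b.stoichiometry is not None)),
    ("participant detection method",
     lambda r: (r.participant_a.participant_detection_methods
                or r.participant_b.participant_detection_methods)),
]


def validate_record(record: InteractionEvidence, dialect: str = "2.7") -> List[str]:
    """Check a record against its invariants and a dialect; never raises.

    Returns one human-readable violation per broken invariant: missing
    primary identifiers, negative stoichiometry, fields populated that the
    dialect cannot carry, invalid dates.
    """
    violations: List[str] = []
    a, b = record.participant_a, record.participant_b
    if not a.primary_ids:
        violations.append("participant A: missing primary identifier")
    if not b.primary_ids and not b.is_empty():
        violations.append("participant B: missing primary identifier")
    for side, p in (("A", a), ("B", b)):
        if p.stoichiometry is not None and p.stoichiometry < 0:
            violations.append(f"participant {side}: negative stoichiometry")
    for name, date in (("creation date", record.creation_date),
                       ("update date", record.update_date)):
        if date is not None and not isinstance(date, _dt.date):
            violations.append(f"{name} is not a valid calendar date")
    if dialect not in ("2.5", "2.6", "2.7"):
        violations.append(f"unknown dialect {dialect!r}")
        return violations
    gated = []
    if dialect == "2.5":
        gated = _FIELDS_26 + _FIELDS_27
    elif dialect == "2.6":
        gated = _FIELDS_27
    for name, populated in gated:
        if populated(record):
            violations.append(f"{name} not available in MITAB {dialect}")
    return violations
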