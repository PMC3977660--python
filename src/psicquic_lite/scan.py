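"""Reference query evaluator: a naive per-record predicate interpreter.

This evaluator answers a normalized MIQL tree by scanning every record and
testing it directly — no index, no postings, no set algebra.  It exists as
an executable definition of the query semantics and as the cross-check the
test suite runs the inverted-index engine against; it is deliberately slow
(O(records × clauses)) and deliberately shares no evaluation code with
:mod:`psicquic_lite.query_engine`.
"""

from __future__ import annotations

from typing import List, Sequence

from .mitab_model import InteractionEvidence
from .miql import (
    DEFAULT_FIELDS, FIELDS, And, MatchAll, Not, Or, Phrase, QueryNode,
    RangeQuery, Term, Wildcard, mentions_field,
)

__all__ = ["record_matches", "scan_matches"]

# Characters that end a word when tokenizing a stored value; identifier
# punctuation (":", "-", "_", ".") is not among them.
_BREAKERS = set(' \t\n\r\f\v,;()"|')


def _words(value: str) -> List[str]:
    words, buf = [], []
    for char in value.lower():
        if char in _BREAKERS:
            if buf:
                words.append("".join(buf))
                buf = []
        else:
            buf.append(char)
    if buf:
        words.append("".join(buf))
    return words


def _field_values(record: InteractionEvidence, field: str) -> List[str]:
    return FIELDS[field].accessor(record)


def _term_hits(record, field, text) -> bool:
    fields = (field,) if field else DEFAULT_FIELDS
    for name in fields:
        for value in _field_values(record, name):
            if text == value.lower() or text in _words(value):
                return True
    return False


def _phrase_hits(record, field, text) -> bool:
    fields = (field,) if field else DEFAULT_FIELDS
    for name in fields:
        for value in _field_values(record, name):
            if value.lower() == text:
                return True
    return False


def _wildcard_hits(record, field, prefix) -> bool:
    fields = (field,) if field else DEFAULT_FIELDS
    for name in fields:
        for value in _field_values(record, name):
            if value.lower().startswith(prefix):
                return True
            if any(word.startswith(prefix) for word in _words(value)):
                return True
    return False


def _range_hits(record, node: RangeQuery) -> bool:
    if FIELDS[node.field].value_kind not in ("integer", "date"):
        raise ValueError(f"range query on non-ordered field {node.field!r}")
    low, high = int(node.low), int(node.high)
    for value in _field_values(record, node.field):
        try:
            number = int(value)
        except ValueError:
            continue
        if node.inclusive and low <= number <= high:
            return True
        if not node.inclusive and low < number < high:
            return True
    return False


def record_matches(record: InteractionEvidence, node: QueryNode) -> bool:
    """Does one record satisfy a normalized query tree?"""
    if isinstance(node, MatchAll):
        return True
    if isinstance(node, Term):
        return _term_hits(record, node.field, node.text)
    if isinstance(node, Phrase):
        return _phrase_hits(record, node.field, node.text)
    if isinstance(node, Wildcard):
        return _wildcard_hits(record, node.field, node.prefix)
    if isinstance(node, RangeQuery):
        return _range_hits(record, node)
    if isinstance(node, Not):
        return not record_matches(record, node.child)
    if isinstance(node, And):
        return all(record_matches(record, child) for child in node.children)
    if isinstance(node, Or):
        return any(record_matches(record, child) for child in node.children)
    raise TypeError(f"not a QueryNode: {node!r}")


def scan_matches(records: Sequence[InteractionEvidence], node: QueryNode,
                 *, exclude_negative: bool = True) -> List[int]:
    """Positions of all matching records, by full scan.

    Applies the same negative-evidence visibility rule as the engine:
    negative records are hidden unless the query mentions ``negative``.
    """
    show_negative = not exclude_negative or mentions_field(node, "negative")
    return [position for position, record in enumerate(records)
            if (show_negative or not record.negative)
            and record_matches(record, node)]
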