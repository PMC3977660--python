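"""In-memory inverted index and MIQL evaluation.

A collection of interaction records is indexed once, single-pass: for every
queryable field, each record's stored string values are tokenized
(lower-cased, split on whitespace and light punctuation; identifiers such
as ``MI:0407`` stay whole) and posted to ``field → token → positions``.
Boolean evaluation is set algebra over postings; phrases match the
untokenized, case-folded stored value; ranges compare integer/date fields
numerically.

Negative evidences (records asserting an interaction does NOT occur) are
excluded from results unless the query itself mentions the ``negative``
field; the behaviour is configurable per index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as _field
from typing import Dict, Iterable, List, Optional, Set

from .mitab_model import InteractionEvidence
from .miql import (
    DEFAULT_FIELDS, FIELDS, And, MatchAll, Not, Or, Phrase, QueryNode,
    RangeQuery, Term, Wildcard, mentions_field, normalize, parse,
)

__all__ = ["IndexedCollection", "SearchResult", "build_index", "evaluate",
           "search", "facet", "tokenize_value"]

_WORD = re.compile(r"[^\s,;()\"|]+")


def tokenize_value(value: str) -> Set[str]:
    """Tokens of one stored value: the whole value case-folded plus its
    words.  Identifier-internal colons/dashes are preserved."""
    lowered = value.lower()
    tokens = set(_WORD.findall(lowered))
    tokens.add(lowered)
    return tokens


@dataclass
class IndexedCollection:
    """Inverted index over an ordered record collection."""

    records: List[InteractionEvidence]
    postings: Dict[str, Dict[str, Set[int]]]
    stored: Dict[str, List[List[str]]]          # field -> per-record raw values
    negative_positions: Set[int]
    dialect: Optional[str] = None
    exclude_negative: bool = True

    @property
    def all_positions(self) -> Set[int]:
        return set(range(len(self.records)))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SearchResult:
    """One page of matches; ``total`` is paging-invariant."""

    total: int
    first: int
    records: List[InteractionEvidence]
    positions: List[int] = _field(default_factory=list)


def build_index(records: Iterable[InteractionEvidence], *,
                dialect: Optional[str] = None,
                exclude_negative: bool = True) -> IndexedCollection:
    """Index a record collection in a single pass."""
    records = list(records)
    postings: Dict[str, Dict[str, Set[int]]] = {name: {} for name in FIELDS}
    stored: Dict[str, List[List[str]]] = {name: [] for name in FIELDS}
    negative: Set[int] = set()
    for position, record in enumerate(records):
        if record.negative:
            negative.add(position)
        for name, descriptor in FIELDS.items():
            values = descriptor.accessor(record)
            stored[name].append(values)
            field_postings = postings[name]
            for value in values:
                for token in tokenize_value(value):
                    field_postings.setdefault(token, set()).add(position)
    return IndexedCollection(records, postings, stored, negative,
                             dialect=dialect, exclude_negative=exclude_negative)


class EvaluationError(ValueError):
    pass


def _require_field(index: IndexedCollection, name: Optional[str]) -> None:
    if name is not None and name not in FIELDS:
        raise EvaluationError(f"unknown field {name!r}")


def _term_positions(index: IndexedCollection, field: Optional[str],
                    token: str) -> Set[int]:
    fields = (field,) if field else DEFAULT_FIELDS
    out: Set[int] = set()
    for name in fields:
        out |= index.postings[name].get(token, set())
    return out


def _phrase_positions(index: IndexedCollection, field: Optional[str],
                      text: str) -> Set[int]:
    fields = (field,) if field else DEFAULT_FIELDS
    out: Set[int] = set()
    for name in fields:
        for position, values in enumerate(index.stored[name]):
            if position in out:
                continue
            if any(v.lower() == text for v in values):
                out.add(position)
    return out


def _wildcard_positions(index: IndexedCollection, field: Optional[str],
                        prefix: str) -> Set[int]:
    fields = (field,) if field else DEFAULT_FIELDS
    out: Set[int] = set()
    for name in fields:
        for token, positions in index.postings[name].items():
            if token.startswith(prefix):
                out |= positions
    return out


def _range_positions(index: IndexedCollection, node: RangeQuery) -> Set[int]:
    descriptor = FIELDS.get(node.field)
    if descriptor is None or descriptor.value_kind not in ("integer", "date"):
        raise EvaluationError(
            f"range query on non-ordered field {node.field!r}")
    try:
        low, high = int(node.low), int(node.high)
    except ValueError:
        raise EvaluationError(
            f"non-numeric range bounds {node.low!r}..{node.high!r}")
    out: Set[int] = set()
    for position, values in enumerate(index.stored[node.field]):
        for value in values:
            try:
                number = int(value)
            except ValueError:
                continue
            if (low <= number <= high if node.inclusive
                    else low < number < high):
                out.add(position)
                break
    return out


def _evaluate(index: IndexedCollection, node: QueryNode) -> Set[int]:
    if isinstance(node, MatchAll):
        return index.all_positions
    if isinstance(node, Term):
        _require_field(index, node.field)
        return _term_positions(index, node.field, node.text)
    if isinstance(node, Phrase):
        _require_field(index, node.field)
        return _phrase_positions(index, node.field, node.text)
    if isinstance(node, Wildcard):
        _require_field(index, node.field)
        return _wildcard_positions(index, node.field, node.prefix)
    if isinstance(node, RangeQuery):
        return _range_positions(index, node)
    if isinstance(node, Not):
        return index.all_positions - _evaluate(index, node.child)
    if isinstance(node, And):
        result: Optional[Set[int]] = None
        for child in node.children:
            positions = _evaluate(index, child)
            result = positions if result is None else result & positions
            if not result:
                return set()
        return result or set()
    if isinstance(node, Or):
        result: Set[int] = set()
        for child in node.children:
            result |= _evaluate(index, child)
        return result
    raise EvaluationError(f"cannot evaluate {node!r}")


def evaluate(index: IndexedCollection, node: QueryNode) -> List[int]:
    """Evaluate a normalized tree; returns sorted matching positions.

    Negative records are dropped unless the query mentions the ``negative``
    field (or the index was built with ``exclude_negative=False``).
    """
    matches = _evaluate(index, node)
    if index.exclude_negative and not mentions_field(node, "negative"):
        matches -= index.negative_positions
    return sorted(matches)


def _sort_positions(index: IndexedCollection, positions: List[int],
                    sort: str) -> List[int]:
    descending = sort.startswith("-")
    name = sort.lstrip("+-")
    descriptor = FIELDS.get(name)
    if descriptor is None:
        raise EvaluationError(f"unknown sort field {name!r}")
    numeric = descriptor.value_kind in ("integer", "date")

    def key(position: int):
        values = index.stored[name][position]
        if not values:
            return (1, 0 if numeric else "", position)
        first_value = values[0]
        if numeric:
            try:
                return (0, int(first_value), position)
            except ValueError:
                return (1, 0, position)
        return (0, first_value.lower(), position)

    if descending:
        # missing-value records stay last; present values reversed
        present = sorted((p for p in positions if key(p)[0] == 0), key=key,
                         reverse=True)
        missing = sorted(p for p in positions if key(p)[0] == 1)
        return present + missing
    return sorted(positions, key=key)


def search(index: IndexedCollection, query: str, first: int = 0,
           max_results: Optional[int] = None,
           sort: Optional[str] = None) -> SearchResult:
    """Parse, evaluate and page a MIQL query.

    ``first``/``max_results`` window the result; ``total`` always reports
    the full match count.  ``sort`` names a field, with a ``-`` prefix for
    descending order; default order is record insertion order.
    """
    if first < 0 or (max_results is not None and max_results < 0):
        raise ValueError("paging parameters must be non-negative")
    node = normalize(parse(query))
    positions = evaluate(index, node)
    if sort:
        positions = _sort_positions(index, positions, sort)
    total = len(positions)
    stop = total if max_results is None else min(total, first + max_results)
    page = positions[first:stop]
    return SearchResult(total, first, [index.records[p] for p in page], page)


def facet(index: IndexedCollection, node: QueryNode, field: str) -> Dict[str, int]:
    """Per-value record counts of *field* over the query's matches.

    A record carrying a value contributes one count to it regardless of
    multiplicity; a record with several distinct values contributes to each
    (so counts can sum to more than the match total)."""
    if field not in FIELDS:
        raise EvaluationError(f"unknown facet field {field!r}")
    counts: Dict[str, int] = {}
    for position in evaluate(index, node):
        for value in set(index.stored[field][position]):
            counts[value] = counts.get(value, 0) + 1
    return counts
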