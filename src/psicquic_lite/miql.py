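"""MIQL — the Molecular Interactions Query Language.

MIQL is a fielded boolean query syntax in the Lucene style: bare terms,
quoted phrases, ``field:value`` clauses, ``AND`` / ``OR`` / ``NOT``
(uppercase), parentheses, trailing-``*`` wildcards and ``[low TO high]``
ranges on ordered fields.  This module defines the queryable field
registry (which record fields each MIQL field reads), the tokenizer, a
recursive-descent parser producing a :class:`QueryNode` tree, a
normalizer, and a renderer whose output re-parses to the same tree.

Grammar (EBNF, precedence NOT > AND > OR, implicit operator = AND)::

    query   := or
    or      := and ("OR" and)*
    and     := not (("AND")? not)*
    not     := "NOT" not | primary
    primary := "(" or ")" | clause
    clause  := [FIELD ":"] (term | phrase | range)
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

from .mitab_model import InteractionEvidence, Participant

__all__ = [
    "FieldDescriptor", "FIELDS", "FIELD_ALIASES", "DEFAULT_FIELDS",
    "QueryNode", "Term", "Phrase", "Wildcard", "RangeQuery", "Not", "And", "Or",
    "MatchAll", "MiqlSyntaxError", "tokenize", "parse", "normalize", "render",
    "mentions_field",
]


# ---------------------------------------------------------------------------
# Field registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldDescriptor:
    """One queryable MIQL field.

    ``accessor`` maps a record to its stored string values for this field;
    ``value_kind`` is one of token, integer, date, boolean (integer and
    date fields support range queries and numeric sorting).
    """

    miql_name: str
    value_kind: str
    accessor: Callable[[InteractionEvidence], List[str]]
    description: str = ""


def _xrefs(refs) -> List[str]:
    out = []
    for r in refs:
        out.append(r.identifier)
        out.append(f"{r.database}:{r.identifier}")
    return out


def _terms(terms) -> List[str]:
    out = []
    for t in terms:
        out.append(t.identifier)
        if t.label:
            out.append(t.label)
    return out


def _aliases(aliases) -> List[str]:
    out = []
    for a in aliases:
        out.append(a.name)
        out.append(f"{a.database}:{a.name}")
    return out


def _taxid(participant: Participant) -> List[str]:
    org = participant.taxid
    if org is None:
        return []
    out = [str(org.taxid)]
    if org.name:
        out.append(org.name)
    return out


def _identifier(rec, participant) -> List[str]:
    return (_xrefs(participant.primary_ids) + _xrefs(participant.alt_ids)
            + _aliases(participant.aliases))


def _annotations(rec) -> List[str]:
    out = []
    for ann in (rec.interaction_annotations
                + rec.participant_a.annotations + rec.participant_b.annotations):
        out.append(ann.topic)
        if ann.text:
            out.append(ann.text)
    return out


def _udate(rec) -> List[str]:
    date = rec.update_date or rec.creation_date
    return [date.strftime("%Y%m%d")] if date is not None else []


def _bool_value(flag: bool) -> List[str]:
    return ["true" if flag else "false"]


def _both(fn) -> Callable[[InteractionEvidence], List[str]]:
    return lambda r: fn(r.participant_a) + fn(r.participant_b)


def _field_table() -> Dict[str, FieldDescriptor]:
    f = FieldDescriptor
    a, b = (lambda r: r.participant_a), (lambda r: r.participant_b)
    table = [
        f("idA", "token", lambda r: _xrefs(a(r).primary_ids), "primary ids of A"),
        f("idB", "token", lambda r: _xrefs(b(r).primary_ids), "primary ids of B"),
        f("id", "token",
          lambda r: _xrefs(a(r).primary_ids) + _xrefs(b(r).primary_ids),
          "primary ids of either participant"),
        f("alias", "token",
          lambda r: _aliases(a(r).aliases) + _aliases(b(r).aliases),
          "aliases of either participant"),
        f("identifier", "token",
          lambda r: _identifier(r, a(r)) + _identifier(r, b(r)),
          "primary + alternative ids + aliases of either participant"),
        f("pubauth", "token", lambda r: list(r.first_authors), "first author"),
        f("pubid", "token", lambda r: _xrefs(r.publication_ids), "publication id"),
        f("taxidA", "integer", lambda r: _taxid(a(r)), "NCBI taxid of A"),
        f("taxidB", "integer", lambda r: _taxid(b(r)), "NCBI taxid of B"),
        f("species", "integer", lambda r: _taxid(a(r)) + _taxid(b(r)),
          "NCBI taxid of either participant"),
        f("detmethod", "token", lambda r: _terms(r.detection_methods),
          "interaction detection method"),
        f("type", "token", lambda r: _terms(r.interaction_types), "interaction type"),
        f("interaction_id", "token", lambda r: _xrefs(r.interaction_ids),
          "interaction identifier"),
        f("pbioroleA", "token", lambda r: _terms(a(r).biological_role)),
        f("pbioroleB", "token", lambda r: _terms(b(r).biological_role)),
        f("pbiorole", "token", _both(lambda p: _terms(p.biological_role))),
        f("pexproleA", "token", lambda r: _terms(a(r).experimental_role)),
        f("pexproleB", "token", lambda r: _terms(b(r).experimental_role)),
        f("pexprole", "token", _both(lambda p: _terms(p.experimental_role))),
        f("ptypeA", "token", lambda r: _terms(a(r).interactor_type)),
        f("ptypeB", "token", lambda r: _terms(b(r).interactor_type)),
        f("ptype", "token", _both(lambda p: _terms(p.interactor_type))),
        f("pxrefA", "token", lambda r: _xrefs(a(r).xrefs)),
        f("pxrefB", "token", lambda r: _xrefs(b(r).xrefs)),
        f("pxref", "token", _both(lambda p: _xrefs(p.xrefs))),
        f("xref", "token", lambda r: _xrefs(r.interaction_xrefs), "interaction xref"),
        f("annot", "token", _annotations, "annotation topics and text"),
        f("udate", "date", _udate, "update date as yyyymmdd"),
        f("negative", "boolean", lambda r: _bool_value(r.negative),
          "negative-evidence flag"),
        f("complex", "token",
          lambda r: _terms([r.expansion_method]) if r.expansion_method else [],
          "complex-expansion method of a derived binary pair"),
        f("ftypeA", "token", lambda r: [ft.feature_type for ft in a(r).features]),
        f("ftypeB", "token", lambda r: [ft.feature_type for ft in b(r).features]),
        f("ftype", "token",
          _both(lambda p: [ft.feature_type for ft in p.features])),
        f("pmethodA", "token", lambda r: _terms(a(r).participant_detection_methods)),
        f("pmethodB", "token", lambda r: _terms(b(r).participant_detection_methods)),
        f("pmethod", "token",
          _both(lambda p: _terms(p.participant_detection_methods))),
        f("stc", "boolean",
          lambda r: _bool_value(a(r).stoichiometry is not None
                                or b(r).stoichiometry is not None),
          "whether stoichiometry information is present"),
        f("param", "boolean", lambda r: _bool_value(bool(r.parameters)),
          "whether interaction parameters are present"),
    ]
    return {d.miql_name: d for d in table}


#: Canonical registry of queryable fields (data-driven; amend here).
FIELDS: Dict[str, FieldDescriptor] = _field_table()

#: Accepted synonyms resolved by :func:`normalize`.
FIELD_ALIASES: Dict[str, str] = {"taxid": "species", "author": "pubauth"}

#: Fields searched by an unfielded term.
DEFAULT_FIELDS: Tuple[str, ...] = (
    "identifier", "alias", "pubid", "species", "detmethod", "type",
    "interaction_id", "xref",
)


# ---------------------------------------------------------------------------
# Query AST
# ---------------------------------------------------------------------------

class QueryNode:
    __slots__ = ()


@dataclass(frozen=True)
class Term(QueryNode):
    text: str
    field: Optional[str] = None


@dataclass(frozen=True)
class Phrase(QueryNode):
    text: str
    field: Optional[str] = None


@dataclass(frozen=True)
class Wildcard(QueryNode):
    prefix: str
    field: Optional[str] = None


@dataclass(frozen=True)
class MatchAll(QueryNode):
    """The ``*`` (or Lucene ``*:*``) query: every visible record."""


@dataclass(frozen=True)
class RangeQuery(QueryNode):
    field: str
    low: str
    high: str
    inclusive: bool = True


@dataclass(frozen=True)
class Not(QueryNode):
    child: QueryNode


@dataclass(frozen=True)
class And(QueryNode):
    children: Tuple[QueryNode, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("And requires at least two children")


@dataclass(frozen=True)
class Or(QueryNode):
    children: Tuple[QueryNode, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("Or requires at least two children")


class MiqlSyntaxError(ValueError):
    def __init__(self, message: str, position: int = -1):
        self.position = position
        suffix = f" at position {position}" if position >= 0 else ""
        super().__init__(message + suffix)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_SPECIAL = set('()[]{}"')
_FIELD_NAME = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


@dataclass(frozen=True)
class _Token:
    kind: str  # FIELD TERM PHRASE AND OR NOT TO ( ) [ ] { }
    text: str
    position: int


def tokenize(query: str) -> List[_Token]:
    """Lex a MIQL query; raises :class:`MiqlSyntaxError` on unbalanced quotes."""
    tokens: List[_Token] = []
    i, n = 0, len(query)
    after_field = False
    while i < n:
        c = query[i]
        if c.isspace():
            i += 1
            continue
        if c == '"':
            text, j = _read_phrase(query, i)
            tokens.append(_Token("PHRASE", text, i))
            i = j
            after_field = False
            continue
        if c in "()[]{}":
            tokens.append(_Token(c, c, i))
            i += 1
            after_field = False
            continue
        j = i
        while j < n and not query[j].isspace() and query[j] not in _SPECIAL:
            j += 1
        run = query[i:j]
        if (not after_field and ":" in run
                and _FIELD_NAME.match(run.split(":", 1)[0] or " ")):
            name, rest = run.split(":", 1)
            tokens.append(_Token("FIELD", name, i))
            if rest:
                tokens.append(_Token("TERM", rest, i + len(name) + 1))
                after_field = False
            else:
                after_field = True
            i = j
            continue
        if not after_field and run in ("AND", "OR", "NOT", "TO"):
            tokens.append(_Token(run, run, i))
        else:
            tokens.append(_Token("TERM", run, i))
        after_field = False
        i = j
    return tokens


def _read_phrase(query: str, i: int):
    buf, j = [], i + 1
    while j < len(query):
        c = query[j]
        if c == "\\" and j + 1 < len(query):
            buf.append(query[j + 1])
            j += 2
            continue
        if c == '"':
            return "".join(buf), j + 1
        buf.append(c)
        j += 1
    raise MiqlSyntaxError("unclosed quote", i)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: List[_Token], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> _Token:
        token = self.peek()
        if token is None:
            raise MiqlSyntaxError("unexpected end of query", len(self.source))
        self.pos += 1
        return token

    def expect(self, kind: str) -> _Token:
        token = self.peek()
        if token is None or token.kind != kind:
            at = token.position if token else len(self.source)
            found = repr(token.text) if token else "end of query"
            raise MiqlSyntaxError(f"expected {kind!r}, found {found}", at)
        return self.take()

    # query := or
    def parse_query(self) -> QueryNode:
        node = self.parse_or()
        if self.peek() is not None:
            token = self.peek()
            raise MiqlSyntaxError(f"unexpected token {token.text!r}", token.position)
        return node

    def parse_or(self) -> QueryNode:
        children = [self.parse_and()]
        while self.peek() is not None and self.peek().kind == "OR":
            self.take()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> QueryNode:
        children = [self.parse_not()]
        while True:
            token = self.peek()
            if token is None or token.kind in ("OR", ")"):
                break
            if token.kind == "AND":
                self.take()
                token = self.peek()
                if token is None:
                    raise MiqlSyntaxError("dangling AND", len(self.source))
            children.append(self.parse_not())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_not(self) -> QueryNode:
        token = self.peek()
        if token is not None and token.kind == "NOT":
            self.take()
            return Not(self.parse_not())
        return self.parse_primary()

    def parse_primary(self) -> QueryNode:
        token = self.peek()
        if token is None:
            raise MiqlSyntaxError("unexpected end of query", len(self.source))
        if token.kind == "(":
            self.take()
            if self.peek() is not None and self.peek().kind == ")":
                raise MiqlSyntaxError("empty parentheses", self.peek().position)
            node = self.parse_or()
            self.expect(")")
            return node
        if token.kind == "FIELD":
            return self.parse_fielded()
        if token.kind in ("TERM", "PHRASE"):
            return self.parse_value(None)
        raise MiqlSyntaxError(f"unexpected token {token.text!r}", token.position)

    def parse_fielded(self) -> QueryNode:
        field_token = self.take()
        name = FIELD_ALIASES.get(field_token.text, field_token.text)
        descriptor = FIELDS.get(name)
        if descriptor is None:
            raise MiqlSyntaxError(f"unknown field {field_token.text!r}",
                                  field_token.position)
        token = self.peek()
        if token is not None and token.kind in ("[", "{"):
            return self.parse_range(descriptor)
        return self.parse_value(descriptor.miql_name)

    def parse_range(self, descriptor: FieldDescriptor) -> QueryNode:
        opener = self.take()
        inclusive = opener.kind == "["
        if descriptor.value_kind not in ("integer", "date"):
            raise MiqlSyntaxError(
                f"range query on non-ordered field {descriptor.miql_name!r}",
                opener.position)
        low = self.expect("TERM").text
        self.expect("TO")
        high = self.expect("TERM").text
        closer = self.take()
        if closer.kind not in ("]", "}"):
            raise MiqlSyntaxError("unterminated range", closer.position)
        return RangeQuery(descriptor.miql_name, low, high, inclusive)

    def parse_value(self, field: Optional[str]) -> QueryNode:
        token = self.take()
        if token.kind == "PHRASE":
            return Phrase(token.text, field)
        if token.kind != "TERM":
            raise MiqlSyntaxError(
                f"expected a term after field, found {token.text!r}", token.position)
        text = token.text
        if field is None and text in ("*", "*:*"):
            return MatchAll()
        if text.startswith("*"):
            raise MiqlSyntaxError("leading wildcards are not supported",
                                  token.position)
        if text.endswith("*"):
            prefix = text[:-1]
            if "*" in prefix:
                raise MiqlSyntaxError("only a single trailing * is supported",
                                      token.position)
            if not prefix:
                raise MiqlSyntaxError("bare * is not a valid term", token.position)
            return Wildcard(prefix, field)
        if "*" in text:
            raise MiqlSyntaxError("only trailing wildcards are supported",
                                  token.position)
        return Term(text, field)


def parse(query: str) -> QueryNode:
    """Parse a MIQL query string into a :class:`QueryNode` tree."""
    if not query or not query.strip():
        raise MiqlSyntaxError("empty query")
    return _Parser(tokenize(query), query).parse_query()


# ---------------------------------------------------------------------------
# Normalization and rendering
# ---------------------------------------------------------------------------

def normalize(node: QueryNode) -> QueryNode:
    """Lower-case term/phrase text (the index is case-insensitive), resolve
    field aliases, flatten nested And/Or of the same variant, and cancel
    double negation."""
    if isinstance(node, Term):
        return Term(node.text.lower(), _canonical(node.field))
    if isinstance(node, Phrase):
        return Phrase(node.text.lower(), _canonical(node.field))
    if isinstance(node, Wildcard):
        return Wildcard(node.prefix.lower(), _canonical(node.field))
    if isinstance(node, RangeQuery):
        return RangeQuery(_canonical(node.field), node.low.lower(),
                          node.high.lower(), node.inclusive)
    if isinstance(node, MatchAll):
        return node
    if isinstance(node, Not):
        child = normalize(node.child)
        if isinstance(child, Not):
            return child.child
        return Not(child)
    if isinstance(node, (And, Or)):
        flat: List[QueryNode] = []
        for child in node.children:
            child = normalize(child)
            if type(child) is type(node):
                flat.extend(child.children)
            else:
                flat.append(child)
        return type(node)(tuple(flat))
    raise TypeError(f"not a QueryNode: {node!r}")


def _canonical(field: Optional[str]) -> Optional[str]:
    if field is None:
        return None
    name = FIELD_ALIASES.get(field, field)
    if name not in FIELDS:
        raise MiqlSyntaxError(f"unknown field {field!r}")
    return name


def render(node: QueryNode) -> str:
    """Serialize a tree back to query text; ``normalize(parse(render(t)))``
    equals ``normalize(t)``."""
    prefix = lambda f: f"{f}:" if f else ""
    if isinstance(node, MatchAll):
        return "*"
    if isinstance(node, Term):
        return f"{prefix(node.field)}{node.text}"
    if isinstance(node, Phrase):
        escaped = node.text.replace("\\", "\\\\").replace('"', '\\"')
        return f'{prefix(node.field)}"{escaped}"'
    if isinstance(node, Wildcard):
        return f"{prefix(node.field)}{node.prefix}*"
    if isinstance(node, RangeQuery):
        lo, hi = ("[", "]") if node.inclusive else ("{", "}")
        return f"{node.field}:{lo}{node.low} TO {node.high}{hi}"
    if isinstance(node, Not):
        return f"NOT {_wrap(node.child)}"
    if isinstance(node, And):
        return " AND ".join(_wrap(c) for c in node.children)
    if isinstance(node, Or):
        return " OR ".join(_wrap(c) for c in node.children)
    raise TypeError(f"not a QueryNode: {node!r}")


def _wrap(node: QueryNode) -> str:
    text = render(node)
    return f"({text})" if isinstance(node, (And, Or)) else text


def mentions_field(node: QueryNode, field: str) -> bool:
    """True when any clause of the tree targets *field* (used for the
    negative-record visibility rule)."""
    if isinstance(node, (Term, Phrase, Wildcard)):
        return node.field == field
    if isinstance(node, RangeQuery):
        return node.field == field
    if isinstance(node, Not):
        return mentions_field(node.child, field)
    if isinstance(node, (And, Or)):
        return any(mentions_field(c, field) for c in node.children)
    return False
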