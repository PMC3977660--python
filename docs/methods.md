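# Methods

This note records how psicquic-lite models the interaction-data formats
and query semantics it implements, the choices made where the standards
are silent, and what the synthetic test collections do and do not show.

## The record model

One `InteractionEvidence` is one MITAB line: two `Participant` slots plus
interaction-level provenance (detection methods, publication, source
database, interaction ids, confidences, annotations, parameters, dates,
checksums) and three semantically loaded fields:

* `negative` — the evidence asserts the interaction does **not** occur;
* `expansion_method` — set if and only if the binary pair was derived
  from an n-ary observation rather than observed as binary;
* per-participant `stoichiometry`, `features` and
  `participant_detection_methods` — the MITAB 2.7 additions that make a
  record MIMIx-complete. An intra-molecular interaction is a record whose
  participant B is entirely empty.

Validation (`validate_record`) never raises: it returns one violation per
broken invariant, including "field populated that the target dialect
cannot carry", which also drives loss detection on down-conversion.

## The column-value grammar

MITAB columns hold `|`-separated values of the shape
`db:accession(free text)`. The published format does not define an
escaping rule, so this package fixes one — the de-facto 2.6+ convention —
and makes it exactly reversible:

* an atom containing any of `| ( ) : " TAB NL`, a comma inside feature
  ranges, leading/trailing whitespace, or equal to the `-` sentinel, is
  wrapped in double quotes;
* inside quotes, `\"` and `\\` escape quote and backslash; tab, newline
  and carriage return are written `\t` `\n` `\r` so a serialized line
  never contains a raw tab or newline (quoting alone would not guarantee
  that, because the column separator is the tab itself);
* an unquoted identifier may itself contain colons (`psi-mi:MI:0407(...)`
  appears in real provider files): everything between the first `:` and
  the trailing `(...)` group is the accession.

`parse_values ∘ format_values` is the identity on well-formed values;
this is property-tested with values dense in reserved characters.
Feature ranges (`1-10`, `?-?`, `n-n`) are kept as opaque verbatim
strings: fuzzy positions make numeric interpretation lossy and no range
algebra is needed anywhere downstream. Dates use `yyyy/mm/dd`;
unparseable dates and stoichiometries are reported as per-line issues
rather than crashing or silently dropping the line.

## Dialects and I/O

The three dialects are strict column-prefix extensions (15 → 36 → 42
columns). The standard's tables group the added columns but do not print
an absolute order, so the order is fixed once, in `mitab_io.COLUMNS`,
following the conventional 2.6/2.7 column sequence; a correction touches
that one table. Reading is line-streaming with constant memory; a single
leading `#` header line is tolerated and never written; blank lines are
skipped with a warning; files are UTF-8. Taxid columns may carry several
renderings of the same taxon in the wild; the model stores one `Organism`
per participant and writes one value, which is lossless for everything
this package itself produces.

## MIQL

The grammar is Lucene-flavoured: `field:value` clauses, quoted phrases,
trailing-`*` wildcards, inclusive `[a TO b]` / exclusive `{a TO b}`
ranges, `AND`/`OR`/`NOT` (uppercase only; lowercase words are terms),
parentheses, and `*` / `*:*` for match-all. Decisions taken where the
language definition is loose:

* **Default operator between adjacent clauses is AND.** Lucene's default
  is OR; a conjunctive default gives precise federated queries and is the
  deployed behaviour this package mirrors.
* **Unfielded terms** search the documented default-field set
  {identifier, alias, pubid, species, detmethod, type, interaction_id,
  xref}.
* **Field names are case-sensitive; term text is case-insensitive**
  (the index folds case at build time, `normalize` folds query text).
* **Wildcards are trailing-only** — leading wildcards defeat a term
  index and are rejected with a clear error.
* The field registry (`miql.FIELDS`) is data-driven: each entry names the
  record accessor and a value kind (token / integer / date / boolean).
  Ranges and numeric sorting are permitted exactly on integer/date
  fields. `stc` and `param` are presence booleans; `complex` matches the
  expansion-method term, which is what lets a user separate expanded
  pairs from original binaries.

`parse` is total on the documented grammar and raises a structured
`MiqlSyntaxError` with a position otherwise (fuzz-tested); `render` is a
right inverse of `parse` up to `normalize` (print/parse fixpoint).

## Query evaluation

`build_index` makes one pass over the records and posts, for every field,
each stored value's tokens (the whole value case-folded, plus its
whitespace/punctuation-split words — identifier-internal `:` `-` `_` `.`
are preserved so `MI:0407` stays one token). Evaluation is set algebra
over postings: And = intersection, Or = union, Not = complement within
the collection; Phrase is an exact case-insensitive match against the
untokenized stored value (MITAB values are atomic); Range converts stored
values and bounds to integers.

**Negative evidences are excluded from every result unless the query
mentions the `negative` field** (configurable per index). This mirrors
deployed provider behaviour: a negative evidence silently matching
`species:9606` would look like a positive interaction to a client.

Sorting is by the first stored value of the sort field (numeric for
integer/date fields, case-folded lexicographic otherwise), ties broken by
insertion order, records missing the field last. Faceting counts
*records* per distinct stored value — a record contributes once to each
distinct value it carries, so facet columns can sum to more than the
match total; counting records rather than value occurrences is the
documented choice. Paging never changes `total`.

The package ships a second, deliberately naive evaluator
(`psicquic_lite.scan`): a per-record predicate interpreter with its own
tokenizer and no shared evaluation code. It is the executable definition
of the semantics; the test suite requires the indexed engine to agree
with it on hundreds of randomized queries, and the two are kept
independent so a bug in one cannot hide in the other.

## Complex expansion

The three standard models are implemented with fixed orientation so
output is deterministic: spoke puts the bait in slot A against each of
the n−1 other participants; matrix emits all n(n−1)/2 unordered pairs in
participant order; bipartite creates a complex pseudo-participant
(caller-supplied accession, interactor type "complex") in slot A against
each of the n members. Every produced record carries the expansion term
in its expansion-method field; the conventional PSI-MI labels are used
and the accessions are parameters, since providers differ. Expansion is
defined for n ≥ 2; single-participant input is an error, and spoke
without a designated bait is an error that points at matrix as the
alternative.

## REST service and registry

The service is a plain WSGI application (stdlib `wsgiref` serves it; any
WSGI server would do). The interactor and interaction endpoints are
implemented as literal rewrites to `identifier:"{id}"` and
`interaction_id:"{id}"` query-endpoint calls, which makes their
byte-equivalence a construction rather than a coincidence. `count`
returns the full match total regardless of paging; every search response
carries the total in `X-PSICQUIC-Count` (the contract names no header, so
this one is fixed and documented). `maxResults` defaults to unlimited:
output is streamed line-by-line, so there is no reason to cap it.
`xml25`/`rdf*`/`biopax` are recognized format tokens that answer 406 —
those conversions are out of scope here, and saying so explicitly beats a
silent 404.

XGMML export is generated as text chunks with proper XML escaping, nodes
interleaved with edges on first sight: memory is bounded by the
distinct-interactor table, never by the record count, so arbitrarily
large results stream without truncation. The suite streams a
50,000-record export under `tracemalloc` and validates the document with
lxml.

The registry is a JSON-configured list of `ServiceEntry` rows served with
the conventional `?action=STATUS|ACTIVE|INACTIVE&format=xml|txt`
interface. `txt` is the minimal `name=rest_url` listing (the serialization
is unspecified upstream; this one is documented and versioned), `xml`
round-trips every field. `refresh_counts` polls each service's count
endpoint with the match-all query; failures mark the entry inactive and
never propagate.

## Synthetic collections

`fixtures.generate` builds collections from a 100-interactor pool with
uniprot-style accessions, four taxa, four detection methods and three
interaction types, at any dialect; the canonical suite-wide collection is
n = 500, seed = 42, dialect 2.7, 10% negative records. Negative flags are
assigned by an even deterministic spread (exactly ⌊n·f⌋ negatives), every
7th-ish record is stamped as spoke-expanded, update dates advance one day
per record from 2010-01-01, and 2.7 extras (stoichiometry, features,
participant detection methods) are laid down on fixed strides — so every
query dimension has known, constructed answers. The answer key (canned
queries, facet truths, negative/visible position sets) is produced by the
generator's own bookkeeping while it builds each record; it is never
obtained by searching, which is what makes the engine/oracle/answer-key
three-way agreement a real test. Identifier shapes deliberately include
embedded colons and multi-word labels to exercise tokenization edges.

What the fixtures do **not** emulate: real interactome topology (degree
distributions, modularity), real controlled-vocabulary breadth, multi-
valued taxid columns, or provider-specific quirks in free-text columns.
Passing tests therefore demonstrate format and query correctness, not
biological realism, and a provider's real file may still exercise parser
paths the generator does not (the non-strict reader with per-line issue
collection exists for exactly that case).

## Problem sizes and determinism

The suite and the acceptance script use the canonical 500-record
collection for query/REST checks, 200 randomized queries for the
engine-vs-oracle comparison, n = 2..12 for expansion, 50,000 records for
the streaming export, and two live local services for the registry check;
these sizes make every property deterministic to verify while keeping a
full run in the tens of seconds. All randomness flows from explicit
seeds: the same `FixtureSpec` yields byte-identical files, and the
acceptance script derives every stream from its `--seed` argument.

## Known limitations

* SOAP/WSDL binding, PSI-XML input/output, RDF/BioPAX serializations and
  relevance ranking are out of scope; the REST routes carry the full
  method semantics.
* The index is in-memory and rebuilt from the MITAB file at startup —
  appropriate up to a few million records; there is no sharding.
* The record model stores per-participant taxids singly, not as
  multi-valued renderings; byte-level round-trip is guaranteed for files
  this package writes, semantic round-trip for files it reads.
* One WSGI worker serves requests sequentially; put a real WSGI server in
  front for concurrent load.
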