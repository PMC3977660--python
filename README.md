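# psicquic-lite

A self-hostable molecular-interaction query service in pure Python: the
PSI-MITAB 2.5/2.6/2.7 interaction formats, the MIQL query language with an
in-memory inverted-index engine, spoke/matrix/bipartite complex expansion,
the PSICQUIC REST interaction-service contract with streamed MITAB and
XGMML output, and a provider registry.

## The problem

Molecular-interaction databases (IntAct, MINT, BioGRID, DIP, ...) each
hold experimentally supported *binary interaction evidences*: "protein A
was observed to interact with protein B, by method M, in publication P".
Federated access to these resources rests on two community standards:

* **PSI-MITAB**, a tab-delimited record format. One line is one binary
  evidence; versions 2.5, 2.6 and 2.7 carry 15, 36 and 42 columns, each
  later version a strict column-prefix extension of the previous one.
  Columns are `|`-separated multi-values of the shape
  `db:accession(free text)` — e.g. `psi-mi:"MI:0407"(direct interaction)` —
  with `-` for an empty column. The 2.6/2.7 extensions add, among others,
  the *negative* flag (evidence an interaction does **not** occur), the
  *complex expansion* method, per-participant *features* and
  *stoichiometry* — enough to carry MIMIx-complete records.
* **MIQL**, a Lucene-style fielded boolean query language
  (`species:9606 AND detmethod:"MI:0018"`, ranges
  `udate:[20100101 TO 20120101]`, wildcards, `NOT`), evaluated by every
  provider behind a common REST URL scheme, so one query can be fanned out
  across the whole federation.

This package implements that provider stack end to end, so a lab can put
its own MITAB file behind the standard interface — and so the formats,
query semantics and expansion operators can be tested offline against
constructed ground truth.

## What is inside

| module | contents |
|---|---|
| `psicquic_lite.mitab_model` | typed record model (`InteractionEvidence`, `Participant`, controlled terms, xrefs, features...), the column-value grammar (`parse_values` / `format_values`), record validation per dialect |
| `psicquic_lite.mitab_io` | streaming reader/writer for 15/36/42-column files, dialect detection, up/down conversion |
| `psicquic_lite.miql` | field registry, tokenizer, recursive-descent parser, normalizer, renderer |
| `psicquic_lite.query_engine` | inverted index, boolean evaluation, paging, sorting, faceting |
| `psicquic_lite.scan` | naive full-scan reference evaluator (the oracle the engine is tested against) |
| `psicquic_lite.expansion` | spoke (n−1), matrix (n(n−1)/2), bipartite (n) expansion of n-ary interactions, each output stamped with its expansion term |
| `psicquic_lite.rest_service` | WSGI app for `/current/search/query/{miql}` and friends; `count`, `tab25/26/27` and chunk-streamed `xgmml` formats |
| `psicquic_lite.registry` | service directory with STATUS/ACTIVE/INACTIVE queries, xml/txt serializations and live count refresh |
| `psicquic_lite.fixtures` | deterministic synthetic collections with engine-independent answer keys |

## Worked example

```python
from psicquic_lite import build_index, search
from psicquic_lite.fixtures import CANONICAL_SPEC, generate

records, key = generate(CANONICAL_SPEC)   # 500 synthetic records, seed 42
index = build_index(records, dialect="2.7")
for miql in ('species:9606 AND detmethod:"MI:0018"',
             "negative:true", 'complex:"spoke expansion"'):
    print(miql, "->", search(index, miql).total, "records")
```

prints

```
species:9606 AND detmethod:"MI:0018" -> 44 records
negative:true -> 50 records
complex:"spoke expansion" -> 64 records
```

44 records involve a human participant and were detected by two-hybrid
screening (`MI:0018`); exactly 50 of the 500 records are negative
evidences (the generator assigns 10% deterministically) and are visible
*only* because the query names the `negative` field; 64 visible records
are binary pairs derived from n-ary observations by spoke expansion,
identifiable because expansion stamps the record's expansion-method
column. See `examples/` for one runnable script per capability (format
round-trip, querying/faceting, expansion, REST service, registry).

The same stack is available from the shell:

```bash
psicquic-lite fixtures generate --n 500 --seed 42 --dialect 2.7 -o demo/
psicquic-lite query demo/fixture.mitab 'species:9606' --format count
psicquic-lite serve demo/fixture.mitab --port 8080
```

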