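"""Index an interaction collection and query it with MIQL.

MIQL is a fielded boolean language: `species:9606` matches either
participant's taxon, `detmethod:"MI:0018"` is an exact phrase on the
detection method, AND/OR/NOT combine clauses, and `udate:[a TO b]` ranges
over dates.  Negative evidences are hidden unless the query asks for them.
"""

from psicquic_lite import build_index, facet, search
from psicquic_lite.fixtures import CANONICAL_SPEC, generate

records, key = generate(CANONICAL_SPEC)   # 500 synthetic records, seed 42
index = build_index(records, dialect="2.7")

for miql in ('species:9606 AND detmethod:"MI:0018"',
             "taxidA:10090 OR taxidA:4932",
             "udate:[20100101 TO 20110101]",
             "negative:true",
             'complex:"spoke expansion"'):
    result = search(index, miql)
    print(f"{miql!r:55} -> {result.total} records")

page = search(index, "species:9606", first=0, max_results=3)
print(f"\nfirst page of 3 (of {page.total}):")
for record in page.records:
    a = record.participant_a.primary_ids[0].identifier
    b = record.participant_b.primary_ids[0].identifier
    print(f"  {a} - {b}  ({record.detection_methods[0].label})")

print("\ndetection-method facet over all visible records:")
from psicquic_lite.miql import normalize, parse
counts = facet(index, normalize(parse("*")), "detmethod")
for value, count in sorted(counts.items()):
    print(f"  {value}: {count}")
# Facet counts are per matching record: each record contributes once to
# every distinct value it carries (id and label), so columns sum to more
# than the match total.
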