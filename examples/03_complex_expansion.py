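"""Expand one n-ary interaction into binary pairs three ways.

A pull-down that co-purifies 5 molecules is one observation, but MITAB
stores binary rows.  Spoke pairs the bait with each prey (n-1 rows),
matrix enumerates all pairs (n(n-1)/2), bipartite links a complex node to
each member (n).  Every produced row carries its expansion method, so it
can never be mistaken for an originally binary observation.
"""

from psicquic_lite import expand_bipartite, expand_matrix, expand_spoke
from psicquic_lite.fixtures import generate_nary
from psicquic_lite.mitab_model import CrossReference

nary = generate_nary(5, seed=3)          # 5 participants, bait at position 0
bait = nary.participants[0].primary_ids[0].identifier
print(f"n = 5 participants, bait = {bait}\n")

for name, records in (
        ("spoke", expand_spoke(nary)),
        ("matrix", expand_matrix(nary)),
        ("bipartite", expand_bipartite(
            nary, CrossReference("complexportal", "CPX-42")))):
    print(f"{name}: {len(records)} binary records")
    for record in records:
        a = record.participant_a.primary_ids[0].identifier
        b = record.participant_b.primary_ids[0].identifier
        print(f"  {a} - {b}   [{record.expansion_method.label}]")
    print()
# Counts follow n-1 / n(n-1)/2 / n; the spoke pair set is always a subset
# of the matrix pair set when the bait is a member.
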