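"""Complex expansion: turning n-ary interactions into binary pairs.

Interaction detection methods such as co-immunoprecipitation observe sets
of n ≥ 2 molecules at once, but MITAB carries binary pairs.  Three
conventional models bridge the gap:

* **spoke** — the designated bait is paired with each of the n−1 other
  participants (n−1 pairs);
* **matrix** — every unordered pair of participants (n(n−1)/2 pairs);
* **bipartite** — a pseudo-participant standing for the complex itself is
  paired with each member (n pairs).

Every produced record carries its expansion model in the record's
``expansion_method`` field, so expanded pairs remain distinguishable from
originally binary observations; no originally binary record carries one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional

from .mitab_model import (
    ControlledTerm, CrossReference, InteractionEvidence, Participant,
)

__all__ = [
    "NaryInteraction", "SPOKE_TERM", "MATRIX_TERM", "BIPARTITE_TERM",
    "expand_spoke", "expand_matrix", "expand_bipartite", "expand",
]

# Conventional PSI-MI labels; accessions are configurable via the *term*
# keyword of each operation since providers differ.
SPOKE_TERM = ControlledTerm("psi-mi", "MI:1060", "spoke expansion")
MATRIX_TERM = ControlledTerm("psi-mi", "MI:1061", "matrix expansion")
BIPARTITE_TERM = ControlledTerm("psi-mi", "MI:1062", "bipartite expansion")


@dataclass
class NaryInteraction:
    """An n-participant interaction awaiting expansion.

    ``template`` carries the shared interaction-level fields (detection
    method, publication, source...) copied onto every produced pair.
    """

    participants: List[Participant]
    bait_index: Optional[int] = None
    template: InteractionEvidence = field(default_factory=InteractionEvidence)

    def __post_init__(self):
        if len(self.participants) < 2:
            raise ValueError(
                "expansion is defined for n >= 2 participants "
                f"(got {len(self.participants)})")
        if self.bait_index is not None and not (
                0 <= self.bait_index < len(self.participants)):
            raise ValueError(f"bait_index {self.bait_index} out of range")


def _pair(nary: NaryInteraction, a: Participant, b: Participant,
          term: ControlledTerm) -> InteractionEvidence:
    record = copy.deepcopy(nary.template)
    record.participant_a = copy.deepcopy(a)
    record.participant_b = copy.deepcopy(b)
    record.expansion_method = term
    return record


def expand_spoke(nary: NaryInteraction, *,
                 term: ControlledTerm = SPOKE_TERM) -> List[InteractionEvidence]:
    """Bait versus every other participant: n−1 pairs, bait as A."""
    if nary.bait_index is None:
        raise ValueError(
            "spoke expansion requires a designated bait; set bait_index "
            "or use matrix expansion")
    bait = nary.participants[nary.bait_index]
    return [_pair(nary, bait, prey, term)
            for position, prey in enumerate(nary.participants)
            if position != nary.bait_index]


def expand_matrix(nary: NaryInteraction, *,
                  term: ControlledTerm = MATRIX_TERM) -> List[InteractionEvidence]:
    """All unordered pairs in participant order: n(n−1)/2 pairs."""
    participants = nary.participants
    return [_pair(nary, participants[i], participants[j], term)
            for i in range(len(participants))
            for j in range(i + 1, len(participants))]


def expand_bipartite(nary: NaryInteraction, complex_id: CrossReference, *,
                     term: ControlledTerm = BIPARTITE_TERM,
                     ) -> List[InteractionEvidence]:
    """Complex pseudo-node (participant A, identified by *complex_id*)
    versus each member: n pairs."""
    complex_node = Participant(
        primary_ids=[complex_id],
        interactor_type=[ControlledTerm("psi-mi", "MI:0314", "complex")],
    )
    return [_pair(nary, complex_node, member, term)
            for member in nary.participants]


def expand(nary: NaryInteraction, method: str,
           complex_id: Optional[CrossReference] = None) -> List[InteractionEvidence]:
    """Dispatch by method name: "spoke", "matrix" or "bipartite"."""
    if method == "spoke":
        return expand_spoke(nary)
    if method == "matrix":
        return expand_matrix(nary)
    if method == "bipartite":
        if complex_id is None:
            raise ValueError("bipartite expansion requires a complex_id")
        return expand_bipartite(nary, complex_id)
    raise ValueError(f"unknown expansion method {method!r}")
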