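"""Deterministic synthetic MITAB collections with known query answers.

The generator builds a small interactome over a fixed pool of uniprot-style
interactors and controlled-vocabulary pools (taxa, detection methods,
interaction types), at any of the three dialects.  While constructing each
record it keeps its own bookkeeping of which positions carry which values,
and derives from that bookkeeping a set of canned MIQL queries with their
expected answers and per-field facet truths.  The answer key is therefore
ground truth by construction — it is never produced by running a search —
so the query engine can be tested against it offline.

The canonical test collection used throughout the suite is
``FixtureSpec(n_records=500, seed=42, dialect="2.7")``.

The fixtures emulate format and query semantics, not biology: identifier
shapes, embedded-colon accessions, value multiplicity and the
negative/expansion flags are realistic, interactome topology is not.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field as _field
from typing import Dict, List, Optional, Set, Tuple

from .expansion import SPOKE_TERM, NaryInteraction
from .mitab_model import (
    Alias, Annotation, Checksum, Confidence, ControlledTerm, CrossReference,
    Feature, InteractionEvidence, Organism, Parameter, Participant,
)

__all__ = ["FixtureSpec", "AnswerKey", "generate", "generate_records",
           "generate_nary", "write_fixture", "random_queries",
           "stream_records", "CANONICAL_SPEC"]

_TAXA = ((9606, "human"), (10090, "mouse"), (4932, "yeast"), (7227, "fruit fly"))
_DETMETHODS = (("MI:0018", "two hybrid"), ("MI:0096", "pull down"),
               ("MI:0006", "anti bait coimmunoprecipitation"),
               ("MI:0114", "x-ray crystallography"))
_TYPES = (("MI:0915", "physical association"), ("MI:0407", "direct interaction"),
          ("MI:0403", "colocalization"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic collection."""

    n_records: int = 500
    seed: int = 42
    dialect: str = "2.7"
    taxa_pool: Tuple[Tuple[int, str], ...] = _TAXA
    detmethod_pool: Tuple[Tuple[str, str], ...] = _DETMETHODS
    type_pool: Tuple[Tuple[str, str], ...] = _TYPES
    negative_fraction: float = 0.1
    n_interactors: int = 100
    nary_sizes: Tuple[int, ...] = tuple(range(2, 13))

    def __post_init__(self):
        if not (self.taxa_pool and self.detmethod_pool and self.type_pool):
            raise ValueError("value pools must be non-empty")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.dialect == "2.5" and self.negative_fraction > 0:
            raise ValueError(
                "negative records require dialect >= 2.6 (the Negative "
                "column does not exist in MITAB 2.5)")
        if self.dialect not in ("2.5", "2.6", "2.7"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


#: The canonical test collection.
CANONICAL_SPEC = FixtureSpec()


@dataclass
class AnswerKey:
    """Engine-independent ground truth for a generated collection.

    ``canned_queries`` maps MIQL text to the positions a correct engine
    must return (negative-evidence exclusion already applied);
    ``facet_truths`` holds per-field value counts over visible records for
    the match-all query; ``match_all_query`` matches every visible record.
    """

    canned_queries: List[Tuple[str, Set[int]]] = _field(default_factory=list)
    facet_truths: Dict[str, Dict[str, int]] = _field(default_factory=dict)
    match_all_query: str = "*"
    visible_positions: Set[int] = _field(default_factory=set)
    negative_positions: Set[int] = _field(default_factory=set)


def _negative_flags(n: int, fraction: float) -> List[bool]:
    # Bresenham-style deterministic assignment: exactly floor(n * fraction)
    # records are negative, evenly spread.
    flags, acc = [], 0.0
    for _ in range(n):
        acc += fraction
        if acc >= 1.0 - 1e-9:
            acc -= 1.0
            flags.append(True)
        else:
            flags.append(False)
    return flags


@dataclass(frozen=True)
class _Interactor:
    accession: str
    gene: str
    taxon: Tuple[int, str]


def _interactor_pool(spec: FixtureSpec, rng: random.Random) -> List[_Interactor]:
    pool = []
    for i in range(spec.n_interactors):
        accession = f"P{10000 + i:05d}"
        gene = f"GEN{i}"
        taxon = spec.taxa_pool[i % len(spec.taxa_pool)]
        pool.append(_Interactor(accession, gene, taxon))
    return pool


def _participant(interactor: _Interactor) -> Participant:
    taxid, name = interactor.taxon
    return Participant(
        primary_ids=[CrossReference("uniprotkb", interactor.accession)],
        alt_ids=[CrossReference("intact", f"EBI-{20000 + int(interactor.accession[1:])}")],
        aliases=[Alias("uniprotkb", interactor.gene, "gene name")],
        taxid=Organism(taxid, name),
    )


def generate(spec: FixtureSpec = CANONICAL_SPEC
             ) -> Tuple[List[InteractionEvidence], AnswerKey]:
    """Build the collection and its answer key; same spec ⇒ same output."""
    rng = random.Random(spec.seed)
    pool = _interactor_pool(spec, rng)
    negatives = (_negative_flags(spec.n_records, spec.negative_fraction)
                 if spec.dialect != "2.5" else [False] * spec.n_records)
    extended = spec.dialect in ("2.6", "2.7")
    full = spec.dialect == "2.7"

    records: List[InteractionEvidence] = []
    # bookkeeping: field -> value -> positions (visible records only, filled
    # after the negatives are known)
    by_taxid_a: Dict[int, Set[int]] = {}
    by_species: Dict[int, Set[int]] = {}
    by_detmethod: Dict[str, Set[int]] = {}
    by_type_word: Dict[str, Set[int]] = {}
    by_identifier: Dict[str, Set[int]] = {}
    by_pubid: Dict[str, Set[int]] = {}
    dates: List[Optional[str]] = []
    expanded: Set[int] = set()
    with_stoichiometry: Set[int] = set()
    with_feature_a: Set[int] = set()
    detmethod_values: List[Tuple[str, str]] = []
    taxon_values: List[Tuple[Tuple[int, str], Tuple[int, str]]] = []

    for i in range(spec.n_records):
        a = pool[rng.randrange(len(pool))]
        b = pool[rng.randrange(len(pool))]
        while b is a:
            b = pool[rng.randrange(len(pool))]
        detmethod = spec.detmethod_pool[rng.randrange(len(spec.detmethod_pool))]
        itype = spec.type_pool[rng.randrange(len(spec.type_pool))]
        pubmed = str(10_000_000 + rng.randrange(9_000_000))

        record = InteractionEvidence(
            participant_a=_participant(a),
            participant_b=_participant(b),
            detection_methods=[ControlledTerm("psi-mi", detmethod[0], detmethod[1])],
            first_authors=[f"author{rng.randrange(40)} et al. ({2005 + i % 9})"],
            publication_ids=[CrossReference("pubmed", pubmed)],
            interaction_types=[ControlledTerm("psi-mi", itype[0], itype[1])],
            source_databases=[ControlledTerm("psi-mi", "MI:0469", "IntAct")],
            interaction_ids=[CrossReference("intact", f"EBI-I{100000 + i}")],
            confidences=[Confidence("intact-miscore", f"0.{rng.randrange(10, 99)}")],
            negative=negatives[i],
        )
        if extended:
            if i % 7 == 3:
                record.expansion_method = SPOKE_TERM
                expanded.add(i)
                record.participant_a.experimental_role = [
                    ControlledTerm("psi-mi", "MI:0496", "bait")]
                record.participant_b.experimental_role = [
                    ControlledTerm("psi-mi", "MI:0498", "prey")]
            else:
                neutral = ControlledTerm("psi-mi", "MI:0499", "unspecified role")
                record.participant_a.experimental_role = [neutral]
                record.participant_b.experimental_role = [neutral]
            record.update_date = _dt.date(2010, 1, 1) + _dt.timedelta(days=i % 900)
            record.creation_date = record.update_date
            record.interaction_annotations = [
                Annotation("comment", f"curated batch {i % 3}")]
            record.host_organism = Organism(-1, "in vitro")
            record.interaction_checksums = [
                Checksum("rigid", f"RIG{spec.seed}{i:06d}")]
        if full:
            if i % 4 == 0:
                record.participant_a.stoichiometry = 2
                record.participant_b.stoichiometry = 1
                with_stoichiometry.add(i)
            if i % 5 == 0:
                record.participant_a.features = [
                    Feature("binding region", (f"{1 + i % 9}-{10 + i % 9}",))]
                with_feature_a.add(i)
            if i % 3 == 0:
                record.parameters = [Parameter("kd", f"{1 + i % 7}.0e-6", "molar")]
            record.participant_a.participant_detection_methods = [
                ControlledTerm("psi-mi", "MI:0396", "predetermined participant")]
            record.participant_b.participant_detection_methods = [
                ControlledTerm("psi-mi", "MI:0396", "predetermined participant")]

        records.append(record)
        dates.append(record.update_date.strftime("%Y%m%d")
                     if record.update_date else None)
        detmethod_values.append(detmethod)
        taxon_values.append((a.taxon, b.taxon))

        if not negatives[i]:
            by_taxid_a.setdefault(a.taxon[0], set()).add(i)
            by_species.setdefault(a.taxon[0], set()).add(i)
            by_species.setdefault(b.taxon[0], set()).add(i)
            by_detmethod.setdefault(detmethod[0], set()).add(i)
            by_type_word.setdefault(itype[1].split()[0], set()).add(i)
            for acc in (a.accession, b.accession):
                by_identifier.setdefault(acc, set()).add(i)
            by_pubid.setdefault(pubmed, set()).add(i)

    visible = {i for i in range(spec.n_records) if not negatives[i]}
    key = AnswerKey(match_all_query="*",
                    visible_positions=visible,
                    negative_positions=set(
                        i for i, flag in enumerate(negatives) if flag))

    # --- canned queries, answers straight from the bookkeeping ------------
    queries = key.canned_queries
    for taxid, positions in sorted(by_taxid_a.items()):
        queries.append((f"taxidA:{taxid}", set(positions)))
    for mi_id, positions in sorted(by_detmethod.items()):
        queries.append((f'detmethod:"{mi_id}"', set(positions)))
    for word, positions in sorted(by_type_word.items()):
        queries.append((f"type:{word}", set(positions)))
    for accession in sorted(by_identifier)[:3]:
        queries.append((f'identifier:"{accession}"', by_identifier[accession]))
    if by_pubid:
        pubmed = sorted(by_pubid)[0]
        queries.append((f"pubid:{pubmed}", by_pubid[pubmed]))
    taxid0 = spec.taxa_pool[0][0]
    mi0 = spec.detmethod_pool[0][0]
    queries.append((
        f'species:{taxid0} AND detmethod:"{mi0}"',
        by_species.get(taxid0, set()) & by_detmethod.get(mi0, set())))
    queries.append((
        f'species:{taxid0} AND NOT detmethod:"{mi0}"',
        (by_species.get(taxid0, set()) - by_detmethod.get(mi0, set()))))
    if len(spec.taxa_pool) >= 2:
        taxid1 = spec.taxa_pool[1][0]
        queries.append((
            f"taxidA:{taxid0} OR taxidA:{taxid1}",
            by_taxid_a.get(taxid0, set()) | by_taxid_a.get(taxid1, set())))
    if extended:
        queries.append(("negative:true", key.negative_positions))
        queries.append(('complex:"spoke expansion"', expanded & visible))
        lo, hi = "20100101", "20110101"
        queries.append((
            f"udate:[{lo} TO {hi}]",
            {i for i in visible if dates[i] is not None and lo <= dates[i] <= hi}))
    if full:
        queries.append(("stc:true", with_stoichiometry & visible))
        queries.append(("ftypeA:binding", with_feature_a & visible))

    # --- facet truths over visible records --------------------------------
    species_counts: Dict[str, int] = {}
    detmethod_counts: Dict[str, int] = {}
    for i in visible:
        (taxid_a, name_a), (taxid_b, name_b) = taxon_values[i]
        for value in {str(taxid_a), name_a, str(taxid_b), name_b}:
            species_counts[value] = species_counts.get(value, 0) + 1
        mi_id, label = detmethod_values[i]
        for value in {mi_id, label}:
            detmethod_counts[value] = detmethod_counts.get(value, 0) + 1
    key.facet_truths["species"] = species_counts
    key.facet_truths["detmethod"] = detmethod_counts
    return records, key


def generate_records(spec: FixtureSpec = CANONICAL_SPEC) -> List[InteractionEvidence]:
    return generate(spec)[0]


def generate_nary(n: int, seed: int = 42, *, bait_index: int = 0) -> NaryInteraction:
    """A deterministic n-participant interaction with a designated bait."""
    if n < 2:
        raise ValueError("an n-ary interaction needs n >= 2 participants")
    rng = random.Random(seed)
    spec = FixtureSpec(seed=seed)
    pool = _interactor_pool(spec, rng)
    members = [_participant(pool[(seed + k) % len(pool)]) for k in range(n)]
    template = InteractionEvidence(
        detection_methods=[ControlledTerm("psi-mi", "MI:0006",
                                          "anti bait coimmunoprecipitation")],
        publication_ids=[CrossReference("pubmed", str(12_000_000 + seed))],
        interaction_types=[ControlledTerm("psi-mi", "MI:0915",
                                          "physical association")],
        source_databases=[ControlledTerm("psi-mi", "MI:0469", "IntAct")],
        interaction_ids=[CrossReference("intact", f"EBI-C{seed}{n}")],
    )
    return NaryInteraction(members, bait_index=bait_index, template=template)


def random_queries(n: int, seed: int = 0,
                   spec: FixtureSpec = CANONICAL_SPEC) -> List[str]:
    """Deterministic randomized MIQL queries over the fixture vocabulary.

    Mixes fielded terms, quoted phrases, trailing wildcards, ranges,
    unfielded terms, AND/OR/NOT and parenthesized groups — the workload for
    checking the indexed engine against the full-scan reference evaluator.
    """
    rng = random.Random(seed)
    taxa = [str(t) for t, _ in spec.taxa_pool] + [name for _, name in spec.taxa_pool]
    accessions = [f"P{10000 + i:05d}" for i in range(spec.n_interactors)]

    def leaf() -> str:
        choice = rng.randrange(12)
        if choice == 0:
            return f"taxidA:{rng.choice(taxa)}"
        if choice == 1:
            return f"species:{rng.choice(taxa)}"
        if choice == 2:
            mi, label = rng.choice(spec.detmethod_pool)
            return f'detmethod:"{mi}"' if rng.random() < 0.5 \
                else f"detmethod:{label.split()[0]}"
        if choice == 3:
            _, label = rng.choice(spec.type_pool)
            return f"type:{label.split()[-1]}"
        if choice == 4:
            return f'identifier:"{rng.choice(accessions)}"'
        if choice == 5:
            return f"identifier:{rng.choice(accessions).lower()}"
        if choice == 6:
            return f"pubauth:author{rng.randrange(40)}"
        if choice == 7:
            prefix = rng.choice(["P100", "GEN1", "two", "pull"])
            field_name = rng.choice(["identifier", "detmethod", "alias"])
            return f"{field_name}:{prefix}*"
        if choice == 8:
            start = 20100101 + rng.randrange(0, 20000)
            return f"udate:[{start} TO {start + rng.randrange(0, 20000)}]"
        if choice == 9:
            return rng.choice(["negative:true", "negative:false",
                               'complex:"spoke expansion"'])
        if choice == 10:
            return rng.choice(["stc:true", "stc:false", "param:true",
                               "ftypeA:binding", "pmethod:predetermined"])
        return rng.choice(accessions)  # unfielded default-field search

    def tree(depth: int) -> str:
        if depth <= 0 or rng.random() < 0.4:
            clause = leaf()
            return f"NOT {clause}" if rng.random() < 0.15 else clause
        op = rng.choice([" AND ", " OR "])
        children = [tree(depth - 1) for _ in range(rng.choice([2, 2, 3]))]
        text = op.join(f"({c})" if (" AND " in c or " OR " in c) else c
                       for c in children)
        return f"NOT ({text})" if rng.random() < 0.1 else text

    return [tree(2) for _ in range(n)]


def stream_records(n: int, seed: int = 42):
    """Lazily yield *n* minimal 2.5-style records over the interactor pool.

    Intended for large streaming workloads (e.g. XGMML export of tens of
    thousands of records) where materializing the collection or an answer
    key would defeat the purpose.
    """
    rng = random.Random(seed)
    spec = FixtureSpec(seed=seed)
    pool = _interactor_pool(spec, rng)
    for i in range(n):
        a = pool[rng.randrange(len(pool))]
        b = pool[rng.randrange(len(pool))]
        yield InteractionEvidence(
            participant_a=_participant(a),
            participant_b=_participant(b),
            detection_methods=[ControlledTerm("psi-mi", "MI:0018", "two hybrid")],
            publication_ids=[CrossReference("pubmed", str(10_000_000 + i))],
            interaction_types=[ControlledTerm("psi-mi", "MI:0915",
                                              "physical association")],
            source_databases=[ControlledTerm("psi-mi", "MI:0469", "IntAct")],
            interaction_ids=[CrossReference("intact", f"EBI-S{i}")],
        )


def write_fixture(spec: FixtureSpec, mitab_path, answer_key_path=None) -> AnswerKey:
    """Generate and write the MITAB file, plus the answer key as JSON."""
    from .mitab_io import write_file

    records, key = generate(spec)
    write_file(records, spec.dialect, mitab_path)
    if answer_key_path is not None:
        payload = {
            "match_all_query": key.match_all_query,
            "canned_queries": [
                {"miql": text, "positions": sorted(positions)}
                for text, positions in key.canned_queries],
            "facet_truths": key.facet_truths,
            "visible_positions": sorted(key.visible_positions),
            "negative_positions": sorted(key.negative_positions),
        }
        with open(answer_key_path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1)
    return key
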