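"""Inverted index vs the full-scan reference evaluator, paging, faceting."""

import pytest

from psicquic_lite.fixtures import FixtureSpec, generate, random_queries
from psicquic_lite.miql import And, Not, Or, normalize, parse
from psicquic_lite.query_engine import (
    EvaluationError, build_index, evaluate, facet, search,
)
from psicquic_lite.scan import scan_matches


def _node(text):
    return normalize(parse(text))


class TestBuildIndex:
    def test_empty_collection_is_queryable(self):
        index = build_index([])
        assert evaluate(index, _node("species:9606")) == []
        assert search(index, "*").total == 0

    def test_sided_fields_distinguish_participants(self, canonical_records,
                                                   canonical_index):
        record = canonical_records[0]
        taxid_a = record.participant_a.taxid.taxid
        hits = evaluate(canonical_index, _node(f"taxidA:{taxid_a}"))
        assert 0 in hits
        only_b = [p for p in evaluate(canonical_index,
                                      _node(f"taxidB:{taxid_a}"))
                  if canonical_records[p].participant_a.taxid.taxid != taxid_a]
        for position in only_b:
            assert position not in hits

    def test_postings_cardinalities_match_brute_force(self, canonical_records,
                                                      canonical_index):
        # spot-check a token against a direct recount
        hits = evaluate(canonical_index, _node("taxidA:9606"))
        brute = [i for i, r in enumerate(canonical_records)
                 if r.participant_a.taxid.taxid == 9606 and not r.negative]
        assert hits == brute


class TestEvaluate:
    def test_tautology_returns_all_visible(self, canonical_records,
                                           canonical_index):
        hits = evaluate(canonical_index, _node("taxidA:9606 OR NOT taxidA:9606"))
        visible = [i for i, r in enumerate(canonical_records) if not r.negative]
        assert hits == visible

    def test_contradictory_conjunction_is_empty(self, canonical_index):
        node = And((_node("taxidA:9606"), _node("taxidA:10090")))
        assert evaluate(canonical_index, node) == []

    def test_answer_key_agreement(self, canonical_records, canonical_index,
                                  canonical_key):
        for text, expected in canonical_key.canned_queries:
            node = _node(text)
            assert set(evaluate(canonical_index, node)) == expected, text
            assert set(scan_matches(canonical_records, node)) == expected, text

    def test_oracle_equivalence_on_randomized_queries(self, canonical_records,
                                                      canonical_index):
        queries = random_queries(200, seed=17)
        for text in queries:
            node = _node(text)
            engine = evaluate(canonical_index, node)
            brute = scan_matches(canonical_records, node)
            assert engine == brute, text

    def test_de_morgan(self, canonical_index):
        a, b = _node("species:9606"), _node('detmethod:"MI:0018"')
        lhs = evaluate(canonical_index, Not(And((a, b))))
        rhs = evaluate(canonical_index, Or((Not(a), Not(b))))
        assert lhs == rhs

    def test_adding_a_conjunct_never_grows_the_result(self, canonical_index):
        for text in random_queries(30, seed=5):
            base = _node(text)
            narrowed = And((base, _node("taxidA:9606")))
            assert set(evaluate(canonical_index, narrowed)) \
                <= set(evaluate(canonical_index, base))

    def test_negative_records_hidden_unless_mentioned(self, canonical_records,
                                                      canonical_index,
                                                      canonical_key):
        assert canonical_key.negative_positions  # fixture includes negatives
        visible = set(evaluate(canonical_index, _node("*")))
        assert visible.isdisjoint(canonical_key.negative_positions)
        negatives = set(evaluate(canonical_index, _node("negative:true")))
        assert negatives == canonical_key.negative_positions

    def test_range_on_unordered_field_is_an_error(self, canonical_index):
        from psicquic_lite.miql import RangeQuery
        with pytest.raises(EvaluationError):
            evaluate(canonical_index, RangeQuery("detmethod", "1", "2"))


class TestSearch:
    def test_zero_page_keeps_total(self, canonical_index):
        full = search(canonical_index, "species:9606")
        empty = search(canonical_index, "species:9606", max_results=0)
        assert empty.records == [] and empty.total == full.total > 0

    def test_pages_partition_the_result(self, canonical_index):
        full = search(canonical_index, "species:9606")
        pages = []
        first = 0
        while first < full.total:
            page = search(canonical_index, "species:9606", first=first,
                          max_results=7)
            assert page.total == full.total
            pages.extend(page.positions)
            first += 7
        assert pages == full.positions

    def test_negative_paging_rejected(self, canonical_index):
        with pytest.raises(ValueError):
            search(canonical_index, "*", first=-1)
        with pytest.raises(ValueError):
            search(canonical_index, "*", max_results=-2)

    def test_sort_by_udate_matches_comparison_sort(self, canonical_records,
                                                   canonical_index):
        result = search(canonical_index, "species:9606", sort="udate")
        brute = sorted(
            result.positions,
            key=lambda p: (canonical_records[p].update_date, p))
        assert result.positions == brute
        descending = search(canonical_index, "species:9606", sort="-udate")
        assert set(descending.positions) == set(result.positions)
        dates = [canonical_records[p].update_date
                 for p in descending.positions]
        assert dates == sorted(dates, reverse=True)

    def test_sort_puts_missing_values_last(self):
        records, _ = generate(FixtureSpec(n_records=30, seed=9,
                                          dialect="2.5",
                                          negative_fraction=0.0))
        index = build_index(records)
        result = search(index, "*", sort="udate")  # 2.5 has no dates
        assert result.positions == list(range(30))


class TestFacet:
    def test_empty_result_gives_empty_mapping(self, canonical_index):
        assert facet(canonical_index, _node('identifier:"NOPE999"'),
                     "species") == {}

    def test_constructed_counts(self):
        records, _ = generate(FixtureSpec(n_records=10, seed=2,
                                          negative_fraction=0.0,
                                          taxa_pool=((9606, "human"),)))
        index = build_index(records)
        counts = facet(index, _node("*"), "taxidA")
        assert counts["9606"] == 10

    def test_facet_truths_from_generator_bookkeeping(self, canonical_index,
                                                     canonical_key):
        for field_name, truth in canonical_key.facet_truths.items():
            node = _node(canonical_key.match_all_query)
            assert facet(canonical_index, node, field_name) == truth

    def test_counts_bounded_by_total(self, canonical_index):
        node = _node("species:9606")
        total = len(evaluate(canonical_index, node))
        counts = facet(canonical_index, node, "detmethod")
        assert all(0 < count <= total for count in counts.values())
        assert sum(counts.values()) >= total

    def test_unknown_field_rejected(self, canonical_index):
        with pytest.raises(EvaluationError):
            facet(canonical_index, _node("*"), "nonsense")
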