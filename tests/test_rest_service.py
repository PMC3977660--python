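"""REST contract: search routes, metadata, paging, streamed XGMML."""

import tracemalloc

import pytest
from lxml import etree

from psicquic_lite.fixtures import FixtureSpec, generate, stream_records
from psicquic_lite.mitab_io import read_records
from psicquic_lite.mitab_model import validate_record
from psicquic_lite.query_engine import build_index
from psicquic_lite.rest_service import (
    COUNT_HEADER, SUPPORTED_FORMATS, PsicquicApp, stream_xgmml,
)

XGMML_NS = "{http://www.cs.rpi.edu/XGMML}"


@pytest.fixture(scope="module")
def app(small_collection):
    records, _ = small_collection
    return PsicquicApp(build_index(records, dialect="2.7"),
                       provider_name="test-provider")


class TestQueryEndpoint:
    def test_count_of_empty_result_is_zero(self, app):
        status, headers, body = app.get(
            '/current/search/query/identifier:"NOPE"', {"format": "count"})
        assert status == "200 OK"
        assert body == b"0"
        assert headers[COUNT_HEADER] == "0"

    @pytest.mark.parametrize("fmt,width", [("tab25", 15), ("tab26", 36),
                                           ("tab27", 42)])
    def test_tab_bodies_have_dialect_width(self, app, fmt, width):
        _, _, body = app.get("/current/search/query/species:9606",
                             {"format": fmt})
        lines = body.decode().splitlines()
        assert lines
        assert {len(line.split("\t")) for line in lines} == {width}

    def test_tab_bodies_reparse_with_zero_violations(self, app):
        for fmt, dialect in (("tab25", "2.5"), ("tab26", "2.6"),
                             ("tab27", "2.7")):
            _, _, body = app.get("/current/search/query/*", {"format": fmt})
            records = list(read_records(iter(body.decode().splitlines()),
                                        dialect, strict=True))
            assert records
            for record in records:
                assert validate_record(record, dialect) == []

    def test_count_equals_unpaged_line_count(self, app):
        for miql in ("species:9606", "*", 'detmethod:"MI:0018"'):
            _, _, count_body = app.get(f"/current/search/query/{miql}",
                                       {"format": "count"})
            _, _, tab_body = app.get(f"/current/search/query/{miql}",
                                     {"format": "tab27"})
            assert int(count_body) == len(tab_body.decode().splitlines())

    def test_paged_bodies_concatenate_to_unpaged(self, app):
        path = "/current/search/query/species:9606"
        _, headers, unpaged = app.get(path, {"format": "tab27"})
        total = int(headers[COUNT_HEADER])
        pieces = []
        for first in range(0, total, 7):
            _, page_headers, page = app.get(path, {
                "format": "tab27", "firstResult": str(first),
                "maxResults": "7"})
            assert page_headers[COUNT_HEADER] == str(total)
            pieces.append(page)
        assert b"".join(pieces) == unpaged

    def test_syntax_error_is_400_with_parser_message(self, app):
        status, _, body = app.get("/current/search/query/nosuchfield:1", {})
        assert status == "400 Bad Request"
        assert b"nosuchfield" in body

    def test_unknown_format_is_406_listing_supported(self, app):
        for fmt in ("xml25", "biopax", "nonsense"):
            status, _, body = app.get("/current/search/query/*",
                                      {"format": fmt})
            assert status == "406 Not Acceptable"
            for supported in SUPPORTED_FORMATS:
                assert supported.encode() in body

    def test_bad_paging_is_400(self, app):
        status, _, _ = app.get("/current/search/query/*",
                               {"firstResult": "-1"})
        assert status == "400 Bad Request"


class TestEquivalentEndpoints:
    def test_interactor_equals_identifier_query(self, app, small_collection):
        records, _ = small_collection
        accession = records[0].participant_a.primary_ids[0].identifier
        _, _, by_interactor = app.get(
            f"/current/search/interactor/{accession}", {"format": "tab27"})
        _, _, by_query = app.get(
            f'/current/search/query/identifier:"{accession}"',
            {"format": "tab27"})
        assert by_interactor == by_query and by_interactor

    def test_absent_interactor_gives_empty_body(self, app):
        _, headers, body = app.get("/current/search/interactor/NOPE",
                                   {"format": "tab27"})
        assert body == b"" and headers[COUNT_HEADER] == "0"

    def test_interaction_equals_interaction_id_query(self, app,
                                                     small_collection):
        records, _ = small_collection
        interaction = records[3].interaction_ids[0].identifier
        _, _, by_interaction = app.get(
            f"/current/search/interaction/{interaction}", {"format": "tab27"})
        _, _, by_query = app.get(
            f'/current/search/query/interaction_id:"{interaction}"',
            {"format": "tab27"})
        assert by_interaction == by_query and by_interaction

    def test_multi_interactor_conjunction_is_intersection(self, app,
                                                          small_collection):
        records, _ = small_collection
        record = records[0]
        id_a = record.participant_a.primary_ids[0].identifier
        id_b = record.participant_b.primary_ids[0].identifier
        _, _, both = app.get(
            f'/current/search/query/identifier:"{id_a}" AND identifier:"{id_b}"',
            {"format": "tab27"})
        _, _, only_a = app.get(f'/current/search/query/identifier:"{id_a}"',
                               {"format": "tab27"})
        _, _, only_b = app.get(f'/current/search/query/identifier:"{id_b}"',
                               {"format": "tab27"})
        set_a = set(only_a.decode().splitlines())
        set_b = set(only_b.decode().splitlines())
        assert set(both.decode().splitlines()) == set_a & set_b
        assert both  # the seed pair itself co-occurs


class TestMetadata:
    def test_formats_lists_exactly_supported(self, app):
        _, _, body = app.get("/current/search/formats", {})
        assert body.decode().split() == list(SUPPORTED_FORMATS)

    def test_version_and_properties(self, app):
        _, _, version = app.get("/current/search/version", {})
        assert version
        _, _, properties = app.get("/current/search/properties", {})
        lines = dict(line.split("=", 1)
                     for line in properties.decode().splitlines())
        assert lines["psicquic.provider"] == "test-provider"
        _, _, single = app.get("/current/search/property/psicquic.provider", {})
        assert single.decode() == "test-provider"

    def test_unknown_property_is_404(self, app):
        status, _, _ = app.get("/current/search/property/unknown", {})
        assert status == "404 Not Found"


class TestXgmml:
    def test_empty_result_is_valid_empty_graph(self):
        document = "".join(stream_xgmml(iter([])))
        root = etree.fromstring(document.encode())
        assert root.tag == f"{XGMML_NS}graph"
        assert len(root) == 0

    def test_nodes_are_distinct_interactors_edges_are_records(self):
        records, _ = generate(FixtureSpec(n_records=30, seed=5,
                                          n_interactors=8,
                                          negative_fraction=0.0))
        document = "".join(stream_xgmml(iter(records)))
        root = etree.fromstring(document.encode())
        interactors = set()
        for record in records:
            for participant in (record.participant_a, record.participant_b):
                ref = participant.primary_ids[0]
                interactors.add(f"{ref.database}:{ref.identifier}")
        assert len(root.findall(f"{XGMML_NS}node")) == len(interactors)
        assert len(root.findall(f"{XGMML_NS}edge")) == len(records)

    def test_via_http_format_parameter(self, app):
        _, _, body = app.get("/current/search/query/species:9606",
                             {"format": "xgmml"})
        etree.fromstring(body)

    def test_large_export_streams_in_bounded_memory(self, tmp_path):
        n = 50_000
        path = tmp_path / "large.xgmml"
        tracemalloc.start()
        with open(path, "w") as handle:
            for chunk in stream_xgmml(stream_records(n, seed=13)):
                handle.write(chunk)
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        # far below the ~25 MB document: nothing is buffered per record
        assert peak < 30 * 1024 * 1024
        root = etree.parse(str(path)).getroot()
        assert len(root.findall(f"{XGMML_NS}edge")) == n
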