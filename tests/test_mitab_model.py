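"""Column value grammar and record validation."""

import datetime

import pytest
from hypothesis import given, settings, strategies as st

from psicquic_lite.mitab_model import (
    Alias, Annotation, Checksum, Confidence, ControlledTerm, CrossReference,
    Feature, InteractionEvidence, MitabValueError, Organism, Parameter,
    Participant, format_values, parse_values, validate_record,
)


class TestParseValues:
    @pytest.mark.parametrize("raw,kind,expected", [
        ("uniprotkb:P12345|intact:EBI-123", "xref",
         [CrossReference("uniprotkb", "P12345"),
          CrossReference("intact", "EBI-123")]),
        ('psi-mi:"MI:0407"(direct interaction)', "term",
         [ControlledTerm("psi-mi", "MI:0407", "direct interaction")]),
        ("psi-mi:MI:0407(direct interaction)", "term",
         [ControlledTerm("psi-mi", "MI:0407", "direct interaction")]),
        ('binding region:1-10("site A")', "feature",
         [Feature("binding region", ("1-10",), "site A")]),
        ("region:1-10,22-30", "feature",
         [Feature("region", ("1-10", "22-30"))]),
        ("taxid:9606(human)", "organism", [Organism(9606, "human")]),
        ("taxid:-1(in vitro)", "organism", [Organism(-1, "in vitro")]),
        ("intact-miscore:0.75", "confidence",
         [Confidence("intact-miscore", "0.75")]),
        ('comment:"just a note"', "annotation",
         [Annotation("comment", "just a note")]),
        ("kd:2.0e-6(molar)", "parameter", [Parameter("kd", "2.0e-6", "molar")]),
        ("rogid:abc123", "checksum", [Checksum("rogid", "abc123")]),
        ("uniprotkb:BRCA2(gene name)", "alias",
         [Alias("uniprotkb", "BRCA2", "gene name")]),
    ])
    def test_examples(self, raw, kind, expected):
        assert parse_values(raw, kind) == expected

    @pytest.mark.parametrize("kind", ["xref", "term", "alias", "confidence",
                                      "annotation", "parameter", "checksum",
                                      "feature", "organism"])
    def test_dash_is_empty_for_every_kind(self, kind):
        assert parse_values("-", kind) == []

    @pytest.mark.parametrize("raw,kind", [
        ("no-separator", "xref"),
        ('db:"unclosed', "xref"),
        ("db:id(unclosed", "term"),
        ("db:id)extra", "term"),
        ("db:id(x)trailing", "term"),
        ("taxid:notanumber", "organism"),
        ("onlytype", "feature"),
    ])
    def test_malformed_values_raise(self, raw, kind):
        with pytest.raises(MitabValueError):
            parse_values(raw, kind, column="test column")

    def test_error_names_column_and_segment(self):
        with pytest.raises(MitabValueError) as err:
            parse_values("good:ok|bad", "xref", column="ID(s) interactor A")
        assert "ID(s) interactor A" in str(err.value)
        assert "bad" in str(err.value)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            parse_values("a:b", "nonsense")


class TestFormatValues:
    def test_empty_list_renders_dash(self):
        assert format_values([]) == "-"

    def test_canonical_term_rendering(self):
        term = ControlledTerm("psi-mi", "MI:0407", "direct interaction")
        assert format_values([term]) == 'psi-mi:"MI:0407"(direct interaction)'

    def test_reserved_characters_are_quoted(self):
        alias = Alias("uniprotkb", "name with (paren)", "gene name")
        text = format_values([alias])
        assert text == 'uniprotkb:"name with (paren)"(gene name)'
        assert parse_values(text, "alias") == [alias]

    def test_no_raw_tab_or_newline_in_output(self):
        nasty = Annotation("topic\twith", "text\nwith|bars")
        text = format_values([nasty])
        assert "\t" not in text and "\n" not in text
        assert parse_values(text, "annotation") == [nasty]


# Round-trip property: parse_values . format_values == identity, for every
# value kind, over strings dense in reserved characters.
_text = st.text(
    alphabet=st.sampled_from(list(
        'abPZ09 |():"\\\t\n,-_.;*?~' + "'")),
    min_size=1, max_size=12).filter(lambda s: s.strip())
_opt_text = st.one_of(st.just(""), _text)

_values = st.one_of(
    st.builds(CrossReference, _text, _text, _opt_text),
    st.builds(ControlledTerm, _text, _text, _opt_text),
    st.builds(Alias, _text, _text, _opt_text),
    st.builds(Confidence, _text, _opt_text),
    st.builds(Annotation, _text, _opt_text),
    st.builds(Parameter, _text, _text, _opt_text),
    st.builds(Checksum, _text, _text),
    st.builds(Feature, _text,
              st.lists(_text, min_size=1, max_size=3).map(tuple), _opt_text),
    st.builds(Organism, st.integers(-5, 10**7), _opt_text),
)

_KIND_OF = {CrossReference: "xref", ControlledTerm: "term", Alias: "alias",
            Confidence: "confidence", Annotation: "annotation",
            Parameter: "parameter", Checksum: "checksum", Feature: "feature",
            Organism: "organism"}


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(_values, max_size=4))
def test_roundtrip_is_identity(values):
    values = [v for v in values if type(v) is type(values[0])] if values else []
    kind = _KIND_OF[type(values[0])] if values else "xref"
    text = format_values(values)
    assert "\t" not in text and "\n" not in text
    assert parse_values(text, kind) == values
    # "-" <-> [] is a bijection
    assert (text == "-") == (values == [])


class TestValidateRecord:
    def _record(self, **kwargs):
        record = InteractionEvidence(
            participant_a=Participant(
                primary_ids=[CrossReference("uniprotkb", "P1")]),
            participant_b=Participant(
                primary_ids=[CrossReference("uniprotkb", "P2")]),
        )
        for key, value in kwargs.items():
            setattr(record, key, value)
        return record

    def test_compliant_record_has_no_violations(self):
        record = self._record()
        record.participant_a.stoichiometry = 2
        record.creation_date = datetime.date(2012, 1, 1)
        assert validate_record(record, "2.7") == []

    def test_stoichiometry_unavailable_in_25(self):
        record = self._record()
        record.participant_a.stoichiometry = 2
        violations = validate_record(record, "2.5")
        assert any("stoichiometry" in v for v in violations)

    def test_negative_flag_unavailable_in_25_but_fine_in_26(self):
        record = self._record(negative=True)
        assert any("negative" in v for v in validate_record(record, "2.5"))
        assert validate_record(record, "2.6") == []

    def test_missing_primary_id_is_reported(self):
        record = self._record()
        record.participant_a = Participant()
        violations = validate_record(record, "2.7")
        assert violations == ["participant A: missing primary identifier"]

    def test_intra_molecular_empty_b_is_legal(self):
        record = self._record()
        record.participant_b = Participant()
        assert validate_record(record, "2.7") == []

    def test_negative_stoichiometry_is_a_violation(self):
        record = self._record()
        record.participant_b.stoichiometry = -3
        assert any("negative stoichiometry" in v
                   for v in validate_record(record, "2.7"))

    def test_validation_never_raises(self):
        assert isinstance(validate_record(InteractionEvidence(), "2.5"), list)
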