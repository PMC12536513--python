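"""BRAT standoff parsing, consistency checking, span-safe replacement."""

import numpy as np
import pytest

from hipsynth.brat import (HEADER_SEPARATOR, HEADER_TEXT, AnnotatedDocument,
                           BratIntegrityError, BratParseError,
                           EntityAnnotation, OverlapError, TextDocument,
                           apply_replacements, check_consistency,
                           normalize_line_endings, parse_annotation_file,
                           write_document)


class TestParsing:
    def test_single_entity_line(self):
        entities, attributes, events = parse_annotation_file(
            "T1\tPATIENT 0 5\tSandy")
        assert len(entities) == 1 and not attributes and not events
        ent = entities[0]
        assert (ent.tid, ent.category, ent.spans, ent.surface) == (
            "T1", "PATIENT", [(0, 5)], "Sandy")

    def test_empty_input(self):
        assert parse_annotation_file("") == ([], [], [])

    def test_entity_with_attribute(self):
        entities, attributes, _ = parse_annotation_file(
            "T1\tDATE 10 18\t07/17/19\nA1\tUncertain T1")
        assert entities[0].category == "DATE"
        assert attributes[0].name == "Uncertain"
        assert attributes[0].target == "T1"

    def test_discontinuous_spans(self):
        entities, _, _ = parse_annotation_file(
            "T1\tPATIENT 0 4;10 15\tJohn Smith")
        assert entities[0].spans == [(0, 4), (10, 15)]

    def test_event_line(self):
        raw = "T1\tPATIENT 0 5\tSandy\nT2\tDATE 6 14\t07/17/19\n" \
              "E1\tVISIT:T1 When:T2"
        _, _, events = parse_annotation_file(raw)
        assert events[0].trigger == "T1"
        assert events[0].args == [("When", "T2")]

    def test_unknown_line_types_tolerated(self):
        entities, _, _ = parse_annotation_file(
            "T1\tPATIENT 0 5\tSandy\n#1\tAnnotatorNotes T1\tcheck me")
        assert len(entities) == 1

    @pytest.mark.parametrize("raw", [
        "T1\tPATIENT zero 5\tSandy",   # non-integer offsets
        "T1\tPATIENT 5 5\tSandy",      # empty span
        "T1\tPATIENT 7 5\tSandy",      # inverted span
        "T1\tPATIENT\tSandy",          # no offsets
    ])
    def test_malformed_entity_lines_raise(self, raw):
        with pytest.raises(BratParseError):
            parse_annotation_file(raw)

    def test_dangling_attribute_reference(self):
        with pytest.raises(BratIntegrityError):
            parse_annotation_file("A1\tUncertain T9")

    def test_line_ending_normalization(self):
        assert normalize_line_endings("a\r\nb\rc\n") == "a\nb\nc\n"


class TestConsistency:
    def test_well_formed(self, simple_doc):
        assert check_consistency(simple_doc) == []

    def test_surface_mismatch(self):
        doc = AnnotatedDocument(
            text_doc=TextDocument("d", "Sara  came."),
            entities=[EntityAnnotation("T1", "PATIENT", [(0, 5)], "Sandy")])
        violations = check_consistency(doc)
        assert len(violations) == 1 and "surface" in violations[0]

    def test_dangling_attribute(self, simple_doc):
        simple_doc.attributes[0].target = "T9"
        violations = check_consistency(simple_doc)
        assert len(violations) == 1 and "T9" in violations[0]

    def test_out_of_bounds_span(self):
        doc = AnnotatedDocument(
            text_doc=TextDocument("d", "hi"),
            entities=[EntityAnnotation("T1", "PATIENT", [(0, 99)], "hi")])
        assert any("out of bounds" in v for v in check_consistency(doc))


class TestApplyReplacements:
    def test_basic_substitution(self):
        doc = AnnotatedDocument(
            text_doc=TextDocument("d", "Sandy came."),
            entities=[EntityAnnotation("T1", "PATIENT", [(0, 5)], "Sandy")])
        out = apply_replacements(doc, {"T1": "Sara"})
        assert out.text == "Sara came."
        assert out.entities[0].spans == [(0, 4)]
        assert out.entities[0].surface == "Sara"

    def test_identity_plan(self, simple_doc):
        plan = {e.tid: e.surface for e in simple_doc.entities}
        out = apply_replacements(simple_doc, plan)
        assert out.text == simple_doc.text
        assert [e.spans for e in out.entities] == \
            [e.spans for e in simple_doc.entities]

    def test_later_spans_shift(self, simple_doc):
        out = apply_replacements(simple_doc, {"T1": "Alexandria"})
        delta = len("Alexandria") - len("Sandy")
        assert out.entities[1].spans == [(14 + delta, 22 + delta)]
        assert out.text.endswith("07/17/19.")
        assert check_consistency(out) == []

    def test_counts_conserved(self, simple_doc):
        out = apply_replacements(simple_doc, {"T1": "Kim", "T2": "01/02/03"})
        assert out.counts() == simple_doc.counts()

    def test_overlapping_planned_replacements_raise(self):
        text = "Sandy Smith came."
        doc = AnnotatedDocument(
            text_doc=TextDocument("d", text),
            entities=[EntityAnnotation("T1", "PATIENT", [(0, 11)],
                                       "Sandy Smith"),
                      EntityAnnotation("T2", "PATIENT", [(6, 11)], "Smith")])
        with pytest.raises(OverlapError):
            apply_replacements(doc, {"T1": "Kim Jones", "T2": "Lee"})

    def test_unplanned_overlapping_entity_is_clipped(self):
        text = "Sandy Smith came."
        doc = AnnotatedDocument(
            text_doc=TextDocument("d", text),
            entities=[EntityAnnotation("T1", "PATIENT", [(0, 11)],
                                       "Sandy Smith"),
                      EntityAnnotation("T2", "PATIENT", [(6, 11)], "Smith")])
        out = apply_replacements(doc, {"T1": "Kim"})
        assert out.text == "Kim came."
        assert check_consistency(out) == []

    def test_discontinuous_replacement(self):
        text = "Sandy of the Smith family"
        doc = AnnotatedDocument(
            text_doc=TextDocument("d", text),
            entities=[EntityAnnotation("T1", "PATIENT", [(0, 5), (13, 18)],
                                       "Sandy Smith")])
        out = apply_replacements(doc, {"T1": "Kim Jones"})
        assert out.text == "Kim of the Jones family"
        assert out.entities[0].surface == "Kim Jones"
        assert check_consistency(out) == []

    def test_matches_segment_rebuild_oracle(self, random_fixture_builder):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            doc, plan, expected = random_fixture_builder(rng)
            out = apply_replacements(doc, plan)
            assert out.text == expected
            assert check_consistency(out) == []
            assert out.counts() == doc.counts()


class TestWriteDocument:
    def test_round_trip_without_header(self, simple_doc):
        txt, ann = write_document(simple_doc, header_enabled=False)
        assert txt == simple_doc.text
        entities, attributes, events = parse_annotation_file(ann)
        assert [e.spans for e in entities] == \
            [e.spans for e in simple_doc.entities]
        assert [e.surface for e in entities] == \
            [e.surface for e in simple_doc.entities]
        assert len(attributes) == 1 and len(events) == 1

    def test_header_prefix_and_shift(self, simple_doc):
        txt, ann = write_document(simple_doc, header_enabled=True)
        assert txt.startswith(
            "PERSONAL IDENTIFYING INFORMATION (PHI) IN THIS DOCUMENT HAS "
            "BEEN REPLACED WITH SYNTHETIC TEXT.")
        shift = len(HEADER_TEXT + HEADER_SEPARATOR)
        entities, _, _ = parse_annotation_file(ann)
        for orig, new in zip(simple_doc.entities, entities):
            assert new.spans == [(s + shift, e + shift)
                                 for s, e in orig.spans]
        # alignment holds against the emitted text
        for ent in entities:
            s, e = ent.spans[0]
            assert txt[s:e] == ent.surface
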