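"""N-ary event <-> binary relation conversion."""

import pytest

from geniakb.bridge import (
    ConversionError,
    RoleMap,
    event_signature,
    events_to_relations,
    relations_to_events,
)
from geniakb.pajson import Denotation, JsonDocument, RelationAnn
from geniakb.standoff import (
    AstDocument,
    EntityAnnotation,
    EventAnnotation,
    TextSpan,
)
from geniakb.synthcorpus import CorpusConfig, generate_gold


def test_event_with_theme_and_cause_becomes_two_relations(nested_regulation_doc):
    jdoc = events_to_relations(nested_regulation_doc)
    by_obj = {}
    for r in jdoc.relations:
        by_obj.setdefault(r.obj, set()).add((r.pred, r.subj))
    assert by_obj["E3"] == {("themeOf", "E2"), ("causeOf", "T1")}
    # event denotation sits on the trigger span and carries the event type
    e3 = jdoc.denotation_map()["E3"]
    assert (e3.span.begin, e3.span.end) == (6, 15)
    assert e3.obj == "Regulation"


def test_relation_count_equals_total_argument_count(small_corpus):
    for doc in small_corpus.documents:
        jdoc = events_to_relations(doc)
        assert len(jdoc.relations) == sum(len(e.args) for e in doc.events)


def test_consumed_triggers_are_omitted_and_restorable(nested_regulation_doc):
    jdoc = events_to_relations(nested_regulation_doc)
    ids = set(jdoc.denotation_map())
    assert ids == {"T1", "T4", "E1", "E2", "E3"}  # triggers folded into events
    kept = events_to_relations(nested_regulation_doc, keep_triggers=True)
    assert set(kept.denotation_map()) == ids | {"T2", "T3", "T5"}


def test_zero_argument_event_yields_denotation_only():
    doc = AstDocument(
        text="binding assay",
        entities=[EntityAnnotation("T1", "Binding", TextSpan(0, 7))],
        events=[EventAnnotation("E1", "Binding", "T1", ())],
    )
    jdoc = events_to_relations(doc)
    assert len(jdoc.denotations) == 1 and not jdoc.relations


def test_coordinated_themes_share_the_event_object():
    doc = AstDocument(
        text="p50 p65 binding",
        entities=[
            EntityAnnotation("T1", "Protein", TextSpan(0, 3)),
            EntityAnnotation("T2", "Protein", TextSpan(4, 7)),
            EntityAnnotation("T3", "Binding", TextSpan(8, 15)),
        ],
        events=[
            EventAnnotation(
                "E1", "Binding", "T3", (("Theme", "T1"), ("Theme2", "T2"))
            )
        ],
    )
    jdoc = events_to_relations(doc)
    assert {(r.pred, r.obj) for r in jdoc.relations} == {("themeOf", "E1")}
    assert {r.subj for r in jdoc.relations} == {"T1", "T2"}


def test_unmapped_role_raises_conversion_error():
    doc = AstDocument(
        text="p50 localizes",
        entities=[
            EntityAnnotation("T1", "Protein", TextSpan(0, 3)),
            EntityAnnotation("T2", "Localization", TextSpan(4, 13)),
        ],
        events=[
            EventAnnotation("E1", "Localization", "T2", (("Mystery", "T1"),))
        ],
    )
    with pytest.raises(ConversionError, match="Mystery"):
        events_to_relations(doc)


def test_isolated_cause_relation_reconstructs_partial_event():
    """A lone causal link is representable without the theme of its event."""
    jdoc = JsonDocument(
        text="MyD88 dependent signaling",
        denotations=[
            Denotation("T1", TextSpan(0, 5), "Protein"),
            Denotation("E1", TextSpan(6, 15), "Regulation"),
        ],
        relations=[RelationAnn("R1", "causeOf", "T1", "E1")],
    )
    doc = relations_to_events(jdoc)
    (ev,) = doc.events
    assert ev.type == "Regulation"
    assert [(r, doc.entity_map()[t].type) for r, t in ev.args] == [
        ("Cause", "Protein")
    ]


def test_document_without_event_denotations_gives_entities_only():
    jdoc = JsonDocument(
        text="p50 p65",
        denotations=[
            Denotation("T1", TextSpan(0, 3), "Protein"),
            Denotation("T2", TextSpan(4, 7), "Protein"),
        ],
    )
    doc = relations_to_events(jdoc)
    assert len(doc.entities) == 2 and not doc.events


def test_repeated_roles_resuffixed_in_relation_order():
    jdoc = JsonDocument(
        text="p50 p65 bcl binding",
        denotations=[
            Denotation("T1", TextSpan(0, 3), "Protein"),
            Denotation("T2", TextSpan(4, 7), "Protein"),
            Denotation("T3", TextSpan(8, 11), "Protein"),
            Denotation("E1", TextSpan(12, 19), "Binding"),
        ],
        relations=[
            RelationAnn("R1", "themeOf", "T1", "E1"),
            RelationAnn("R2", "themeOf", "T2", "E1"),
            RelationAnn("R3", "themeOf", "T3", "E1"),
        ],
    )
    (ev,) = relations_to_events(jdoc).events
    assert [r for r, _ in ev.args] == ["Theme", "Theme2", "Theme3"]


def test_unknown_predicate_strict_raises_lenient_passes_through():
    jdoc = JsonDocument(
        text="p50 site",
        denotations=[
            Denotation("T1", TextSpan(0, 3), "Protein"),
            Denotation("E1", TextSpan(4, 8), "Binding"),
        ],
        relations=[RelationAnn("R1", "locusOf", "T1", "E1")],
    )
    rmap = RoleMap({"Theme": "themeOf"})
    with pytest.raises(ConversionError, match="locusOf"):
        relations_to_events(jdoc, rmap)
    with pytest.warns(UserWarning, match="locusOf"):
        doc = relations_to_events(jdoc, rmap, strict=False)
    assert any("locusOf" in line for line in doc.opaque_lines)


def test_role_map_must_be_injective():
    with pytest.raises(ConversionError, match="injective"):
        RoleMap({"Theme": "themeOf", "Patient": "themeOf"})


def test_semantic_round_trip_on_100_seeded_documents():
    """events->relations->events preserves every event's (type, trigger span,
    multiset of (base role, target)) and every standalone entity."""
    corpus = generate_gold(CorpusConfig(n_docs=100, seed=23, cause_prob=0.7))
    for doc in corpus.documents:
        back = relations_to_events(events_to_relations(doc))
        assert event_signature(back) == event_signature(doc)


def test_conversion_is_deterministic(small_corpus):
    from geniakb.pajson import serialize_pajson

    doc = small_corpus.documents[0]
    assert serialize_pajson(events_to_relations(doc)) == serialize_pajson(
        events_to_relations(doc)
    )
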