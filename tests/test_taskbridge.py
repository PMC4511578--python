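"""GE <-> GRO concept mapping, ancestor subsumption, conversion statistics."""

import random

import pytest

from geniakb.standoff import (
    AstDocument,
    DocRef,
    EntityAnnotation,
    EventAnnotation,
    TextSpan,
)
from geniakb.taskbridge import (
    ConceptMap,
    ConversionStats,
    Hierarchy,
    UnknownConceptError,
    conversion_stats_report,
    convert_ge_to_gro,
    convert_gro_to_ge,
    convertible_percentages,
    load_default_concept_map,
    load_default_hierarchy,
    nearest_mapped_ancestor,
)

M = load_default_concept_map()
H = load_default_hierarchy()


@pytest.mark.parametrize(
    "gro_concept, ge_concept",
    [
        ("Transcription", "Transcription"),           # direct equivalence
        ("RegulationOfGeneExpression", "Regulation"), # via RegulatoryProcess
        ("TranscriptionFactor", "Protein"),           # two is-a steps
        ("Enzyme", "Protein"),
        ("ProteinSubunit", "Protein"),
        ("ProteinTargeting", "Localization"),
        ("Gene", "Protein"),
        ("TranscriptionOfGene", "Transcription"),
        ("Heterodimerization", "Binding"),
        ("Disease", None),                            # Occurrent branch, unmapped
        ("Organism", None),
        ("BindingOfProteinToDNA", None),              # GRO Binding is unmapped
        ("DNA", None),
        ("NeverHeardOfIt", None),                     # absent from hierarchy
    ],
)
def test_nearest_mapped_ancestor(gro_concept, ge_concept):
    assert nearest_mapped_ancestor(gro_concept, H, M) == ge_concept


def test_nearest_mapped_ancestor_agrees_with_exhaustive_search():
    """BFS-by-level with lexicographic ties equals brute-force minimum-depth
    search over all ancestor paths, on random 50-node hierarchies."""
    rng = random.Random(2024)
    for _ in range(20):
        nodes = [f"C{i}" for i in range(50)]
        edges = []
        for i, child in enumerate(nodes[1:], start=1):
            for parent in rng.sample(nodes[:i], k=min(i, rng.randint(1, 2))):
                edges.append((child, parent))
        h = Hierarchy.from_edges(edges)
        mapped = {c: c.lower() for c in rng.sample(nodes, k=10)}
        m = ConceptMap(ge_to_gro={}, gro_to_ge=mapped)

        def brute(c):
            if c in mapped:
                return mapped[c]
            depth = {c: 0}
            frontier = [c]
            best = None  # (depth, concept name)
            while frontier:
                nxt = []
                for node in frontier:
                    for parent in h.parents(node):
                        if parent not in depth:
                            depth[parent] = depth[node] + 1
                            nxt.append(parent)
                        if parent in mapped:
                            cand = (depth[node] + 1, parent)
                            if best is None or cand < best:
                                best = cand
                frontier = nxt
            return mapped[best[1]] if best else None

        for c in nodes:
            assert nearest_mapped_ancestor(c, h, m) == brute(c), c


def test_hierarchy_rejects_cycles():
    with pytest.raises(ValueError, match="cycle"):
        Hierarchy.from_edges([("A", "B"), ("B", "A")])


def ge_doc():
    text = "p50 p65 binding deacetylation expression"
    entities = [
        EntityAnnotation("T1", "Protein", TextSpan(0, 3)),
        EntityAnnotation("T2", "Protein", TextSpan(4, 7)),
        EntityAnnotation("T3", "Binding", TextSpan(8, 15)),
        EntityAnnotation("T4", "Deacetylation", TextSpan(16, 29)),
        EntityAnnotation("T5", "Gene_expression", TextSpan(30, 40)),
    ]
    events = [
        EventAnnotation("E1", "Binding", "T3", (("Theme", "T1"), ("Theme2", "T2"))),
        EventAnnotation("E2", "Deacetylation", "T4", (("Theme", "T1"),)),
        EventAnnotation("E3", "Gene_expression", "T5", (("Theme", "T2"),)),
    ]
    doc = AstDocument(text, entities, events, DocRef("synth", "ge", 0))
    doc.validate()
    return doc


def test_ge_to_gro_relabels_and_drops_ignored_concepts():
    out, stats = convert_ge_to_gro(ge_doc(), M)
    types = {e.id: e.type for e in out.entities}
    assert types["T3"] == "BindingToProtein"
    assert types["T1"] == "Protein"  # default one-to-many resolution
    assert "T4" not in types  # Deacetylation dropped
    assert {e.type for e in out.events} == {"BindingToProtein", "GeneExpression"}
    assert (stats.entities_convertible, stats.entities_dropped) == (4, 1)
    assert (stats.events_convertible, stats.events_dropped) == (2, 1)


def test_ge_protein_can_map_to_gro_gene():
    m = load_default_concept_map(ge_protein_as="Gene")
    out, _ = convert_ge_to_gro(ge_doc(), m)
    assert out.entity_map()["T1"].type == "Gene"


def test_fully_mapped_document_reports_100_percent():
    doc = ge_doc()
    doc = AstDocument(
        doc.text,
        [e for e in doc.entities if e.type != "Deacetylation"],
        [e for e in doc.events if e.type != "Deacetylation"],
        doc.doc_ref,
    )
    _, stats = convert_ge_to_gro(doc, M)
    assert stats.entities_dropped == stats.events_dropped == 0
    assert convertible_percentages(stats) == (100.0, 100.0)


def test_gro_to_ge_converts_via_ancestors_and_drops_foreign_branches():
    text = "TF enzyme organism targeting"
    entities = [
        EntityAnnotation("T1", "TranscriptionFactor", TextSpan(0, 2)),
        EntityAnnotation("T2", "Organism", TextSpan(3, 9)),
        EntityAnnotation("T3", "ProteinTargeting", TextSpan(10, 19)),
    ]
    events = [EventAnnotation("E1", "ProteinTargeting", "T3", (("Theme", "T1"),))]
    doc = AstDocument(text, entities, events, DocRef("synth", "gro", 0))
    doc.validate()
    out, stats = convert_gro_to_ge(doc, M, H)
    types = {e.id: e.type for e in out.entities}
    assert types == {"T1": "Protein", "T3": "Localization"}
    assert out.events[0].type == "Localization"
    assert (stats.entities_convertible, stats.entities_dropped) == (2, 1)


def test_dropping_an_event_removes_arguments_pointing_at_it():
    text = "p50 express disease"
    entities = [
        EntityAnnotation("T1", "Protein", TextSpan(0, 3)),
        EntityAnnotation("T2", "GeneExpression", TextSpan(4, 11)),
        EntityAnnotation("T3", "Disease", TextSpan(12, 19)),
    ]
    events = [
        EventAnnotation("E1", "Disease", "T3", ()),
        EventAnnotation("E2", "GeneExpression", "T2",
                        (("Theme", "T1"), ("Cause", "E1"))),
    ]
    doc = AstDocument(text, entities, events, DocRef("synth", "gro2", 0))
    doc.validate()
    out, _ = convert_gro_to_ge(doc, M, H)
    (ev,) = out.events
    assert ev.args == (("Theme", "T1"),)  # the dropped Disease argument is gone


def test_strict_mode_raises_on_unknown_concept():
    doc = AstDocument(
        "blob",
        [EntityAnnotation("T1", "Blob", TextSpan(0, 4))],
        [],
        DocRef("synth", "x", 0),
    )
    with pytest.raises(UnknownConceptError):
        convert_ge_to_gro(doc, M, strict=True)
    out, stats = convert_ge_to_gro(doc, M, strict=False)
    assert stats.entities_dropped == 1 and not out.entities


def test_equivalence_round_trip_ge_gro_ge():
    """A GE document using only equivalence-mapped concepts survives
    GE->GRO->GE unchanged."""
    doc = ge_doc()
    doc = AstDocument(
        doc.text,
        [e for e in doc.entities if e.type != "Deacetylation"],
        [e for e in doc.events if e.type != "Deacetylation"],
        doc.doc_ref,
    )
    gro, _ = convert_ge_to_gro(doc, M)
    back, _ = convert_gro_to_ge(gro, M, H)
    assert back.entities == doc.entities
    assert back.events == doc.events


def test_drop_counting_partitions_the_input(small_corpus):
    for doc in small_corpus.documents:
        _, stats = convert_ge_to_gro(doc, M)
        assert (
            stats.entities_convertible + stats.entities_dropped
            == len(doc.entities)
        )
        assert stats.events_convertible + stats.events_dropped == len(doc.events)


def test_surviving_labels_are_in_target_vocabulary(small_corpus):
    gro_vocab = set(M.gro_to_ge) | set(H.is_a) | {"Entity"}
    for doc in small_corpus.documents:
        out, _ = convert_ge_to_gro(doc, M)
        for ann in (*out.entities, *out.events):
            assert ann.type in gro_vocab, ann


def test_stats_report_formats_counts_and_percentages():
    report = conversion_stats_report(
        ConversionStats(6449, 125, 3436, 280)
    )
    assert "6,449\t98.1%" in report
    assert "125\t1.9%" in report
    assert "3,436\t92.5%" in report
    assert "280\t7.5%" in report


def test_stats_report_gro_to_ge_percentages():
    stats = ConversionStats(4193, 3881, 1094, 3188)
    assert convertible_percentages(stats) == (51.9, 25.5)
    report = conversion_stats_report(stats)
    assert "4,193\t51.9%" in report and "48.1%" in report


def test_degenerate_empty_stats_warn():
    report = conversion_stats_report(ConversionStats())
    assert "warning" in report and "0.0%" in report
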