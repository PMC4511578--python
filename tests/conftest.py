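import pytest

from geniakb.bridge import events_to_relations
from geniakb.rdfkb import corpus_to_triples
from geniakb.standoff import (
    AstDocument,
    DocRef,
    EntityAnnotation,
    EventAnnotation,
    TextSpan,
)
from geniakb.synthcorpus import CorpusConfig, generate_gold


@pytest.fixture
def nested_regulation_doc() -> AstDocument:
    """MTb induces NFAT5 gene expression via the MyD88-dependent cascade,
    annotated with two stacked regulation events: the expression of NFAT5
    is the theme of a regulation (signaling) which is the theme of another
    regulation (dependent) whose cause is MyD88."""
    text = "MyD88 dependent signaling induces NFAT5 expression"
    entities = [
        EntityAnnotation("T1", "Protein", TextSpan(0, 5)),       # MyD88
        EntityAnnotation("T2", "Regulation", TextSpan(6, 15)),   # dependent
        EntityAnnotation("T3", "Positive_regulation", TextSpan(16, 25)),
        EntityAnnotation("T4", "Protein", TextSpan(34, 39)),     # NFAT5
        EntityAnnotation("T5", "Gene_expression", TextSpan(40, 50)),
    ]
    events = [
        EventAnnotation("E1", "Gene_expression", "T5", (("Theme", "T4"),)),
        EventAnnotation("E2", "Positive_regulation", "T3", (("Theme", "E1"),)),
        EventAnnotation(
            "E3", "Regulation", "T2", (("Theme", "E2"), ("Cause", "T1"))
        ),
    ]
    doc = AstDocument(text, entities, events, DocRef("synth", "fig1", 0))
    doc.validate()
    return doc


@pytest.fixture
def flat_regulation_doc() -> AstDocument:
    """The schematic variant of ``nested_regulation_doc``: the word
    'dependent' does not trigger its own regulation event; MyD88 attaches
    directly as the cause of the inner regulation."""
    text = "MyD88 dependent signaling induces NFAT5 expression"
    entities = [
        EntityAnnotation("T1", "Protein", TextSpan(0, 5)),
        EntityAnnotation("T3", "Positive_regulation", TextSpan(16, 25)),
        EntityAnnotation("T4", "Protein", TextSpan(34, 39)),
        EntityAnnotation("T5", "Gene_expression", TextSpan(40, 50)),
    ]
    events = [
        EventAnnotation("E1", "Gene_expression", "T5", (("Theme", "T4"),)),
        EventAnnotation(
            "E2", "Positive_regulation", "T3",
            (("Theme", "E1"), ("Cause", "T1")),
        ),
    ]
    doc = AstDocument(text, entities, events, DocRef("synth", "fig1", 0))
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def small_corpus():
    return generate_gold(CorpusConfig(n_docs=12, seed=42, cause_prob=1.0))


@pytest.fixture(scope="session")
def small_corpus_graph(small_corpus):
    return corpus_to_triples(
        events_to_relations(d) for d in small_corpus.documents
    )
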