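"""RDF export of annotation documents under the text annotation ontology (TAO).

Each denotation introduces a *context entity* — an entity defined by the
specific span of text that denotes it.  Per denotation three triples are
emitted: an ``rdf:type`` link to the task concept, an ``rdf:type`` link to
``tao:Context_entity``, and a ``tao:denoted_by`` link to a dereferenceable
span IRI of the form

    {base}/docs/sourcedb/{db}/sourceid/{id}/divs/{div}/spans/{begin}-{end}

Each relation annotation becomes a single triple between the instance IRIs
of its endpoints using a predicate in the task namespace (``genia:themeOf``,
``genia:causeOf``, …).  Only ``tao:denoted_by`` is emitted; its inverse
``tao:denote`` is derivable and left implicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import rdflib
from rdflib import RDF, URIRef

from .pajson import JsonDocument
from .standoff import DocRef, TextSpan

__all__ = [
    "Triple",
    "TripleGraph",
    "NamespaceConfig",
    "DEFAULT_NAMESPACES",
    "span_iri",
    "instance_iri",
    "document_to_triples",
    "corpus_to_triples",
    "serialize_graph",
    "parse_graph",
]

Triple = tuple[str, str, str]

RDF_TYPE = str(RDF.type)


@dataclass(frozen=True)
class NamespaceConfig:
    """Absolute IRI prefixes for the TAO and task vocabularies."""

    tao: str = "http://pubannotation.org/ontology/tao.owl#"
    task: str = "http://bionlp.dbcls.jp/genia#"
    span_base: str = "http://pubannotation.org"
    inst_base: str = "http://bionlp.dbcls.jp/instances"

    def __post_init__(self) -> None:
        for prefix in (self.tao, self.task):
            if not prefix.endswith(("/", "#")):
                raise ValueError(f"namespace prefix must end in / or #: {prefix!r}")

    @property
    def context_entity(self) -> str:
        return self.tao + "Context_entity"

    @property
    def denoted_by(self) -> str:
        return self.tao + "denoted_by"

    def concept(self, label: str) -> str:
        """Task-namespace IRI for a concept label, inserted verbatim."""
        return self.task + label

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NamespaceConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {"tao", "task", "span_base", "inst_base"}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown namespace config keys: {sorted(unknown)}")
        return cls(**cfg)


DEFAULT_NAMESPACES = NamespaceConfig()


@dataclass
class TripleGraph:
    """A named set of IRI triples with deterministic (sorted) iteration."""

    name: str = ""
    triples: set[Triple] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.triples is None:
            self.triples = set()

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self.triples

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self.triples))

    def add(self, t: Triple) -> None:
        self.triples.add(t)

    def union(self, other: "TripleGraph") -> "TripleGraph":
        return TripleGraph(self.name, self.triples | other.triples)

    def to_rdflib(self) -> rdflib.Graph:
        g = rdflib.Graph()
        for s, p, o in self:
            g.add((URIRef(s), URIRef(p), URIRef(o)))
        return g


def span_iri(doc_ref: DocRef, span: TextSpan, cfg: NamespaceConfig = DEFAULT_NAMESPACES) -> str:
    """Dereferenceable IRI for a text span of a document."""
    return (
        f"{cfg.span_base}/docs/sourcedb/{doc_ref.sourcedb}"
        f"/sourceid/{doc_ref.sourceid}/divs/{doc_ref.divid}"
        f"/spans/{span.begin}-{span.end}"
    )


def instance_iri(doc_ref: DocRef, denotation_id: str,
                 cfg: NamespaceConfig = DEFAULT_NAMESPACES) -> str:
    """Deterministic instance IRI for a denotation within a document.

    Gold and system graphs over the same documents share span IRIs (the
    comparable currency) but keep instance IRIs disjoint per annotation set
    only through the denotation ids, which is what query projection onto
    spans relies on.
    """
    d = doc_ref
    return f"{cfg.inst_base}/{d.sourcedb}-{d.sourceid}-{d.divid}#{denotation_id}"


def document_to_triples(doc: JsonDocument,
                        cfg: NamespaceConfig = DEFAULT_NAMESPACES,
                        name: str = "") -> TripleGraph:
    """Emit 3 triples per denotation and 1 per relation (set semantics)."""
    doc.validate()
    g = TripleGraph(name)
    inst = {
        d.id: instance_iri(doc.doc_ref, d.id, cfg) for d in doc.denotations
    }
    for d in doc.denotations:
        g.add((inst[d.id], RDF_TYPE, cfg.concept(d.obj)))
        g.add((inst[d.id], RDF_TYPE, cfg.context_entity))
        g.add((inst[d.id], cfg.denoted_by, span_iri(doc.doc_ref, d.span, cfg)))
    for r in doc.relations:
        g.add((inst[r.subj], cfg.concept(r.pred), inst[r.obj]))
    return g


def corpus_to_triples(docs: Iterable[JsonDocument],
                      cfg: NamespaceConfig = DEFAULT_NAMESPACES,
                      name: str = "") -> TripleGraph:
    """Union of per-document graphs; order-independent by set semantics."""
    g = TripleGraph(name)
    for doc in docs:
        g.triples |= document_to_triples(doc, cfg).triples
    return g


def serialize_graph(g: TripleGraph, format: str = "ntriples") -> bytes:
    """Serialize to N-Triples (sorted statement order) or Turtle."""
    if format == "ntriples":
        body = "".join(
            f"<{s}> <{p}> <{o}> .\n" for s, p, o in g  # iteration is sorted
        )
        return body.encode("utf-8")
    if format == "turtle":
        return g.to_rdflib().serialize(format="turtle").encode("utf-8")
    raise ValueError(f"unknown serialization format {format!r}")


def parse_graph(data: bytes | str, format: str = "ntriples",
                name: str = "") -> TripleGraph:
    """Load a serialized graph back into a TripleGraph."""
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    rg = rdflib.Graph()
    rdflib_fmt = {"ntriples": "nt", "turtle": "turtle"}.get(format)
    if rdflib_fmt is None:
        raise ValueError(f"unknown serialization format {format!r}")
    rg.parse(data=data, format=rdflib_fmt)
    return TripleGraph(name, {(str(s), str(p), str(o)) for s, p, o in rg})
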