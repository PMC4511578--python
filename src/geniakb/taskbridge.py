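"""Corpus conversion between the GE (Genia) and GRO annotation schemata.

The two tasks annotate closely related biology (transcription-factor-centred
gene regulation) with different concept vocabularies.  Conversion relies on
an equivalence table between concepts plus, for the GRO->GE direction, the
GRO is-a hierarchy: a GRO concept without a direct equivalent is converted
through its nearest mapped ancestor (``RegulationOfGeneExpression`` is a
subconcept of ``RegulatoryProcess``, hence converts to ``Regulation``).
Annotations with no mapped concept or ancestor are dropped, and drops are
counted into conversion-rate statistics.

The Genia ``Protein`` maps to both ``Gene`` and ``Protein`` in GRO; the
forward direction resolves this one-to-many case by configuration
(default: ``Protein``).  The GE concepts ``Deacetylation`` and
``Ubiquitination`` have no GRO correspondent and are ignored (dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

from .standoff import AstDocument, EventAnnotation

__all__ = [
    "ConceptMap",
    "Hierarchy",
    "ConversionStats",
    "UnknownConceptError",
    "load_default_concept_map",
    "load_default_hierarchy",
    "nearest_mapped_ancestor",
    "convert_ge_to_gro",
    "convert_gro_to_ge",
    "conversion_stats_report",
    "convertible_percentages",
]


class UnknownConceptError(ValueError):
    """A source concept has no mapping (strict mode only)."""


#: GE'13 concepts with no GRO correspondent; their annotations are dropped.
IGNORED_GE = frozenset({"Deacetylation", "Ubiquitination"})


@dataclass(frozen=True)
class ConceptMap:
    """Equivalence mappings between Genia and GRO concepts."""

    ge_to_gro: dict[str, str]
    gro_to_ge: dict[str, str]
    ignored_ge: frozenset[str] = IGNORED_GE

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]],
                   ge_protein_as: str = "Protein") -> "ConceptMap":
        """Build both directions from (Genia, GRO) equivalence pairs.

        ``ge_protein_as`` resolves the one-to-many Protein mapping for the
        forward direction (``"Protein"`` or ``"Gene"``).
        """
        ge_to_gro: dict[str, str] = {}
        gro_to_ge: dict[str, str] = {}
        for ge, gro in pairs:
            gro_to_ge[gro] = ge
            if ge == "Protein":
                if gro == ge_protein_as:
                    ge_to_gro[ge] = gro
            else:
                ge_to_gro[ge] = gro
        if "Protein" not in ge_to_gro:
            raise ValueError(
                f"ge_protein_as={ge_protein_as!r} is not a GRO target of Protein"
            )
        return cls(ge_to_gro, gro_to_ge)

    @classmethod
    def from_tsv(cls, path: str | Path, ge_protein_as: str = "Protein") -> "ConceptMap":
        pairs = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ge, gro = line.split("\t")
            pairs.append((ge, gro))
        return cls.from_pairs(pairs, ge_protein_as)


@dataclass(frozen=True)
class Hierarchy:
    """An is-a hierarchy as child -> set of parents; must be acyclic."""

    is_a: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(node: str, stack: list[str]) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise ValueError(f"is-a cycle through {node!r}")
            state[node] = 0
            for parent in self.is_a.get(node, ()):
                visit(parent, stack + [node])
            state[node] = 1

        for node in self.is_a:
            visit(node, [])

    def parents(self, c: str) -> frozenset[str]:
        return self.is_a.get(c, frozenset())

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "Hierarchy":
        table: dict[str, set[str]] = {}
        for child, parent in edges:
            table.setdefault(child, set()).add(parent)
        return cls({c: frozenset(ps) for c, ps in table.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Hierarchy":
        edges = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")
            edges.append((child, parent))
        return cls.from_edges(edges)


def load_default_concept_map(ge_protein_as: str = "Protein") -> ConceptMap:
    """The shipped equivalence table between the two task ontologies."""
    path = resources.files("geniakb").joinpath("data/ge_gro_mapping.tsv")
    with resources.as_file(path) as p:
        return ConceptMap.from_tsv(p, ge_protein_as)


def load_default_hierarchy() -> Hierarchy:
    """The shipped synthetic toy GRO is-a hierarchy (see the data file header)."""
    path = resources.files("geniakb").joinpath("data/gro_isa_synthetic.tsv")
    with resources.as_file(path) as p:
        return Hierarchy.from_tsv(p)


def nearest_mapped_ancestor(c: str, h: Hierarchy, m: ConceptMap) -> str | None:
    """GE concept for a GRO concept via the closest mapped is-a ancestor.

    A directly mapped concept wins; otherwise ancestors are searched
    breadth-first by level, ties broken lexicographically by GRO concept
    name.  Returns ``None`` when no ancestor is mapped (the annotation is
    then not convertible).
    """
    if c in m.gro_to_ge:
        return m.gro_to_ge[c]
    level = sorted(h.parents(c))
    seen: set[str] = set(level)
    while level:
        for node in level:  # lexicographic within the level
            if node in m.gro_to_ge:
                return m.gro_to_ge[node]
        nxt: set[str] = set()
        for node in level:
            nxt |= h.parents(node) - seen
        seen |= nxt
        level = sorted(nxt)
    return None


@dataclass
class ConversionStats:
    """Counts of convertible vs dropped annotations for one conversion run."""

    entities_convertible: int = 0
    entities_dropped: int = 0
    events_convertible: int = 0
    events_dropped: int = 0
    #: Convertibility is decided by the annotation's own concept; argument
    #: loss does not reclassify an event.
    policy: str = "type-only"

    def add(self, other: "ConversionStats") -> None:
        self.entities_convertible += other.entities_convertible
        self.entities_dropped += other.entities_dropped
        self.events_convertible += other.events_convertible
        self.events_dropped += other.events_dropped


def _pct(part: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        Decimal(repr(100.0 * part / total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def _convert(doc: AstDocument, map_concept) -> tuple[AstDocument, ConversionStats]:
    stats = ConversionStats()
    kept_entities = []
    entity_ok: dict[str, str] = {}
    for ent in doc.entities:
        target = map_concept(ent.type)
        if target is None:
            stats.entities_dropped += 1
            continue
        stats.entities_convertible += 1
        entity_ok[ent.id] = target
        kept_entities.append(replace(ent, type=target))

    event_target: dict[str, str | None] = {}
    for ev in doc.events:
        event_target[ev.id] = map_concept(ev.type)

    # an event survives iff its own type maps and its trigger survived;
    # iterate because dropping an event may orphan arguments of others
    alive = {
        ev.id
        for ev in doc.events
        if event_target[ev.id] is not None and ev.trigger_id in entity_ok
    }
    kept_events = []
    for ev in doc.events:
        # counting policy is type-only: an event is convertible iff its own
        # concept maps, even if it cannot be materialized for loss of trigger
        if event_target[ev.id] is not None:
            stats.events_convertible += 1
        else:
            stats.events_dropped += 1
        if ev.id not in alive:
            continue
        args = tuple(
            (role, target)
            for role, target in ev.args
            if target in entity_ok or target in alive
        )
        kept_events.append(
            EventAnnotation(ev.id, event_target[ev.id], ev.trigger_id, args)
        )
    out = AstDocument(
        text=doc.text,
        entities=kept_entities,
        events=kept_events,
        doc_ref=doc.doc_ref,
        opaque_lines=list(doc.opaque_lines),
    )
    out.validate()
    return out, stats


def convert_ge_to_gro(doc: AstDocument, m: ConceptMap,
                      *, strict: bool = False) -> tuple[AstDocument, ConversionStats]:
    """Relabel GE concepts to GRO per the equivalence table.

    ``Deacetylation``/``Ubiquitination`` annotations are dropped and counted;
    other unmapped concepts raise in strict mode and count as drops otherwise.
    """
    def map_concept(c: str) -> str | None:
        if c in m.ignored_ge:
            return None
        return m.ge_to_gro.get(c)

    def lenient_map(c: str) -> str | None:
        return map_concept(c)

    if strict:
        def strict_map(c: str) -> str | None:
            if c in m.ignored_ge:
                return None  # ignored by design, never an error
            if c not in m.ge_to_gro:
                raise UnknownConceptError(f"unknown GE concept {c!r}")
            return m.ge_to_gro[c]
        return _convert(doc, strict_map)
    return _convert(doc, lenient_map)


def convert_gro_to_ge(doc: AstDocument, m: ConceptMap, h: Hierarchy,
                      *, strict: bool = False) -> tuple[AstDocument, ConversionStats]:
    """Relabel GRO concepts to GE via nearest mapped is-a ancestors.

    Concepts with no mapped ancestor are dropped and counted (this is the
    normal case for about half the GRO data, e.g. the Organism branch);
    strict mode raises instead.
    """
    def map_concept(c: str) -> str | None:
        target = nearest_mapped_ancestor(c, h, m)
        if target is None and strict:
            raise UnknownConceptError(f"GRO concept {c!r} has no mapped ancestor")
        return target

    return _convert(doc, map_concept)


def conversion_stats_report(stats: ConversionStats) -> str:
    """Tabular report with thousands separators and 1-decimal percentages."""
    ent_total = stats.entities_convertible + stats.entities_dropped
    ev_total = stats.events_convertible + stats.events_dropped
    lines = [f"# convertibility policy: {stats.policy}"]
    if ent_total == 0 and ev_total == 0:
        lines.append("# warning: no annotations counted")
    lines.append("kind\tstatus\tcount\tpercent")
    for kind, conv, drop, total in (
        ("Entities", stats.entities_convertible, stats.entities_dropped, ent_total),
        ("Events", stats.events_convertible, stats.events_dropped, ev_total),
    ):
        lines.append(
            f"{kind}\tConvertible\t{conv:,}\t{_pct(conv, total):.1f}%"
        )
        lines.append(
            f"{kind}\tNon-convertible\t{drop:,}\t{_pct(drop, total):.1f}%"
        )
    return "\n".join(lines)


def convertible_percentages(stats: ConversionStats) -> tuple[float, float]:
    """(entities, events) convertible percentages at 1 decimal, half-up."""
    return (
        _pct(stats.entities_convertible,
             stats.entities_convertible + stats.entities_dropped),
        _pct(stats.events_convertible,
             stats.events_convertible + stats.events_dropped),
    )
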