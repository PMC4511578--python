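"""Seeded synthetic gold corpora and controllably degraded submissions.

The generator emits documents in the style of the gene-regulation event
annotation the evaluator consumes: protein mentions, simple events
(expression, transcription, localization, phosphorylation, binding with
1-3 protein themes), nested regulation chains up to a configurable depth
with an optional protein cause attached at the top, and direct
protein-regulates-protein events.  Text is synthesized as space-joined
tokens so offsets are trivially consistent; prose realism is a non-goal.

Alongside the documents the generator keeps a *ledger* of every
query-relevant fact (which protein is expressed, which pairs bind
collectively, which protein causes which), which serves as a brute-force
oracle for the query engine — the expected result sets are derived from
generation-time bookkeeping, never from the queries themselves.

The perturbation operator degrades a gold corpus into a synthetic
"submission": event deletions, retypings, span shifts, and schematic
rewrites.  A schematic rewrite re-expresses a causal attachment the other
way — expanding a direct cause into an extra regulation layer, or
collapsing one regulation layer of a chain — leaving the transitive
queries' answers unchanged while changing the single-step ones.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .kbquery import ResultSet
from .rdfkb import DEFAULT_NAMESPACES, NamespaceConfig, span_iri
from .standoff import (
    AstDocument,
    DocRef,
    EntityAnnotation,
    EventAnnotation,
    TextSpan,
    base_role,
)

__all__ = [
    "CorpusConfig",
    "PerturbationConfig",
    "GoldLedger",
    "Corpus",
    "generate_gold",
    "perturb",
]

_SIMPLE_TYPES = (
    "Gene_expression",
    "Transcription",
    "Localization",
    "Phosphorylation",
)
_REG_TYPES = ("Regulation", "Positive_regulation", "Negative_regulation")

_PROTEINS = (
    "MyD88", "NFAT5", "IkBa", "RelA", "STAT3", "TRAF6", "IRF4",
    "p65", "p50", "Sox6", "GATA1", "TNFa", "IL2", "Bcl2", "Jun",
)
_TRIGGERS = {
    "Gene_expression": ("expression", "expressed", "production"),
    "Transcription": ("transcription", "transcribed"),
    "Localization": ("localization", "secretion", "translocation"),
    "Phosphorylation": ("phosphorylation", "phosphorylated"),
    "Binding": ("binding", "binds", "interaction"),
    "Regulation": ("regulation", "dependent", "affects"),
    "Positive_regulation": ("induces", "activation", "upregulation"),
    "Negative_regulation": ("inhibits", "suppression", "downregulation"),
}


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for a synthetic gold corpus.

    ``event_type_dist`` mixes the statement kinds; the ``Regulation`` mass
    produces direct protein-regulates-protein events, the others produce a
    simple event whose theme is a protein, optionally wrapped in a
    regulation chain of random depth up to ``max_nesting_depth`` with a
    protein cause attached at the top with probability ``cause_prob``.
    """

    n_docs: int = 20
    mean_entities_per_doc: float = 15.0
    event_type_dist: dict[str, float] = field(
        default_factory=lambda: {
            "Gene_expression": 0.30,
            "Binding": 0.20,
            "Regulation": 0.20,
            "Localization": 0.10,
            "Transcription": 0.10,
            "Phosphorylation": 0.10,
        }
    )
    max_nesting_depth: int = 2
    binding_theme_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.4, 3: 0.2}
    )
    cause_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name, dist in (
            ("event_type_dist", self.event_type_dist),
            ("binding_theme_dist", self.binding_theme_dist),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has a negative probability")
        if self.n_docs < 0 or self.max_nesting_depth < 0:
            raise ValueError("n_docs and max_nesting_depth must be >= 0")
        if not 0.0 <= self.cause_prob <= 1.0:
            raise ValueError("cause_prob must be in [0, 1]")
        if set(self.binding_theme_dist) - {1, 2, 3}:
            raise ValueError("binding theme counts must be 1..3")


@dataclass(frozen=True)
class PerturbationConfig:
    """Independent per-event degradation probabilities."""

    p_delete_event: float = 0.0
    p_retype_event: float = 0.0
    p_span_shift: float = 0.0
    span_shift_max: int = 2
    p_schematic_rewrite: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_delete_event", "p_retype_event", "p_span_shift",
                     "p_schematic_rewrite"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.span_shift_max < 1:
            raise ValueError("span_shift_max must be >= 1")


@dataclass
class GoldLedger:
    """Generation-time bookkeeping of every query-relevant fact.

    Facts are stored as (doc index, begin, end) span keys; materialization
    into span-IRI result sets (including the codepoint ordering of binding
    pairs) happens against a namespace configuration.
    """

    singles: dict[str, set[tuple]] = field(
        default_factory=lambda: {"Q1": set(), "Q2": set(), "Q3": set()}
    )
    pairs: dict[str, set[tuple]] = field(
        default_factory=lambda: {
            "Q4": set(), "Q5": set(), "Q6": set(), "Q7": set(), "Q8": set()
        }
    )
    doc_refs: dict[int, DocRef] = field(default_factory=dict)

    def expected_results(
        self, cfg: NamespaceConfig = DEFAULT_NAMESPACES
    ) -> dict[str, ResultSet]:
        def iri(key: tuple) -> str:
            doc_i, begin, end = key
            return span_iri(self.doc_refs[doc_i], TextSpan(begin, end), cfg)

        out: dict[str, ResultSet] = {}
        for q, keys in self.singles.items():
            out[q] = ResultSet(1, frozenset((iri(k),) for k in keys))
        for q, keys in self.pairs.items():
            rows = set()
            for a, b in keys:
                ia, ib = iri(a), iri(b)
                if q == "Q4":  # unordered pair, oriented by IRI codepoints
                    if ia == ib:
                        continue
                    rows.add((ia, ib) if ia < ib else (ib, ia))
                else:  # directed (theme span, cause span)
                    rows.add((ia, ib))
            out[q] = ResultSet(2, frozenset(rows))
        return out


@dataclass
class Corpus:
    documents: list[AstDocument]
    ledger: GoldLedger


class _DocBuilder:
    def __init__(self, doc_index: int):
        self.tokens: list[str] = []
        self.pos = 0
        self.entities: list[EntityAnnotation] = []
        self.events: list[EventAnnotation] = []
        self.doc_ref = DocRef("synth", str(doc_index), 0)

    def add_token(self, token: str) -> TextSpan:
        begin = self.pos
        self.tokens.append(token)
        self.pos += len(token)
        span = TextSpan(begin, self.pos)
        self.pos += 1  # the joining space (or trailing newline position)
        return span

    def entity(self, etype: str, span: TextSpan) -> str:
        eid = f"T{len(self.entities) + 1}"
        self.entities.append(EntityAnnotation(eid, etype, span))
        return eid

    def event(self, etype: str, trigger: str,
              args: tuple[tuple[str, str], ...]) -> str:
        eid = f"E{len(self.events) + 1}"
        self.events.append(EventAnnotation(eid, etype, trigger, args))
        return eid

    def build(self) -> AstDocument:
        doc = AstDocument(
            text=" ".join(self.tokens),
            entities=self.entities,
            events=self.events,
            doc_ref=self.doc_ref,
        )
        doc.validate()
        return doc


def _choice(rng: random.Random, dist: dict) -> object:
    items = sorted(dist.items(), key=lambda kv: str(kv[0]))
    r = rng.random()
    acc = 0.0
    for value, p in items:
        acc += p
        if r < acc:
            return value
    return items[-1][0]


def generate_gold(cfg: CorpusConfig) -> Corpus:
    """Generate a gold corpus; identical config + seed gives identical output."""
    cfg.validate()
    if cfg.max_nesting_depth > 0 and all(
        cfg.event_type_dist.get(t, 0.0) == 0.0 for t in _SIMPLE_TYPES
    ):
        raise ValueError(
            "infeasible config: nesting depth > 0 but no statement kind that "
            "can carry a regulation chain has probability > 0"
        )
    rng = random.Random(cfg.seed)
    ledger = GoldLedger()
    documents: list[AstDocument] = []
    for doc_i in range(cfg.n_docs):
        b = _DocBuilder(doc_i)
        ledger.doc_refs[doc_i] = b.doc_ref
        # spend an entity budget on statements (each consumes 2-5 entities)
        budget = max(2, round(rng.gauss(cfg.mean_entities_per_doc,
                                        cfg.mean_entities_per_doc / 4)))
        while budget > 0:
            kind = _choice(rng, cfg.event_type_dist)
            if kind == "Binding":
                budget -= _gen_binding(rng, b, cfg, ledger, doc_i)
            elif kind == "Regulation":
                budget -= _gen_direct_regulation(rng, b, ledger, doc_i)
            else:
                budget -= _gen_simple(rng, b, cfg, ledger, doc_i, kind)
        b.add_token(".")
        documents.append(b.build())
    return Corpus(documents, ledger)


def _protein(rng: random.Random, b: _DocBuilder) -> tuple[str, TextSpan]:
    span = b.add_token(rng.choice(_PROTEINS))
    return b.entity("Protein", span), span


def _trigger(rng: random.Random, b: _DocBuilder, etype: str) -> str:
    span = b.add_token(rng.choice(_TRIGGERS[etype]))
    return b.entity(etype, span)


def _gen_simple(rng, b, cfg: CorpusConfig, ledger: GoldLedger, doc_i: int,
                etype: str) -> int:
    """A simple event over one protein, optionally under a regulation chain."""
    pid, pspan = _protein(rng, b)
    trig = _trigger(rng, b, etype)
    ev = b.event(etype, trig, (("Theme", pid),))
    used = 2
    pkey = (doc_i, pspan.begin, pspan.end)
    if etype == "Gene_expression":
        ledger.singles["Q1"].add(pkey)
    elif etype == "Localization":
        ledger.singles["Q2"].add(pkey)

    depth = rng.randint(0, cfg.max_nesting_depth)
    top = ev
    for _ in range(depth):
        rtype = rng.choice(_REG_TYPES)
        rtrig = _trigger(rng, b, rtype)
        top = b.event(rtype, rtrig, (("Theme", top),))
        used += 1
    if depth > 0 and rng.random() < cfg.cause_prob:
        cid, cspan = _protein(rng, b)
        last = b.events[-1]
        b.events[-1] = replace(last, args=last.args + (("Cause", cid),))
        used += 1
        ckey = (doc_i, cspan.begin, cspan.end)
        # the only protein with a themeOf path into the chain top is pid
        ledger.pairs["Q6"].add((pkey, ckey))
        if etype == "Gene_expression":
            ledger.pairs["Q8"].add((pkey, ckey))
            if depth == 1:
                ledger.pairs["Q7"].add((pkey, ckey))
    return used


def _gen_binding(rng, b, cfg: CorpusConfig, ledger: GoldLedger,
                 doc_i: int) -> int:
    k = _choice(rng, cfg.binding_theme_dist)
    pids = [_protein(rng, b) for _ in range(k)]
    trig = _trigger(rng, b, "Binding")
    args = tuple(
        (("Theme" if i == 0 else f"Theme{i + 1}"), pid)
        for i, (pid, _) in enumerate(pids)
    )
    b.event("Binding", trig, args)
    keys = [(doc_i, s.begin, s.end) for _, s in pids]
    ledger.singles["Q3"].update(keys)
    for i, a in enumerate(keys):  # collective binding: all pairs
        for c in keys[i + 1:]:
            ledger.pairs["Q4"].add((a, c))
    return k + 1


def _gen_direct_regulation(rng, b, ledger: GoldLedger, doc_i: int) -> int:
    """Protein X regulates protein Y, expressed as one regulation event."""
    yid, yspan = _protein(rng, b)
    rtype = rng.choice(_REG_TYPES)
    trig = _trigger(rng, b, rtype)
    xid, xspan = _protein(rng, b)
    b.event(rtype, trig, (("Theme", yid), ("Cause", xid)))
    ykey = (doc_i, yspan.begin, yspan.end)
    xkey = (doc_i, xspan.begin, xspan.end)
    ledger.pairs["Q5"].add((ykey, xkey))
    ledger.pairs["Q6"].add((ykey, xkey))
    return 3


def perturb(gold: list[AstDocument], p: PerturbationConfig) -> list[AstDocument]:
    """Degrade a gold corpus into a synthetic system submission.

    Operations apply independently per event (deletion, retyping, schematic
    rewrite) or per protein entity (span shift).  The output is always
    schema-valid; infeasible rewrites are skipped.
    """
    p.validate()
    rng = random.Random(p.seed)
    return [_perturb_doc(doc, p, rng) for doc in gold]


def _perturb_doc(doc: AstDocument, p: PerturbationConfig,
                 rng: random.Random) -> AstDocument:
    entities = {e.id: e for e in doc.entities}
    events = {e.id: e for e in doc.events}
    order = [e.id for e in doc.events]

    # deletions (cascade: arguments referencing a deleted event are removed)
    deleted: set[str] = set()
    for eid in order:
        if p.p_delete_event and rng.random() < p.p_delete_event:
            deleted.add(eid)
    for eid in order:
        if eid in deleted:
            continue
        ev = events[eid]
        kept = tuple((r, t) for r, t in ev.args if t not in deleted)
        if kept != ev.args:
            events[eid] = replace(ev, args=kept)

    # retypings
    for eid in order:
        if eid in deleted or not p.p_retype_event:
            continue
        if rng.random() < p.p_retype_event:
            ev = events[eid]
            pool = [t for t in (*_SIMPLE_TYPES, "Binding", *_REG_TYPES)
                    if t != ev.type]
            events[eid] = replace(ev, type=rng.choice(pool))

    # schematic rewrites (collapse a regulation layer, or expand a cause)
    next_t = max((int(e[1:]) for e in entities), default=0) + 1
    next_e = max((int(e[1:]) for e in events), default=0) + 1
    for eid in list(order):  # snapshot: never rewrite an event minted below
        if eid in deleted or not p.p_schematic_rewrite:
            continue
        if rng.random() >= p.p_schematic_rewrite:
            continue
        ev = events[eid]
        cause = [(r, t) for r, t in ev.args if base_role(r) == "Cause"]
        if len(cause) != 1:
            continue  # nothing to re-express
        (crole, ctarget), rest = cause[0], [
            (r, t) for r, t in ev.args if base_role(r) != "Cause"
        ]
        themes = [t for r, t in rest if base_role(r) == "Theme"]
        inner = events.get(themes[0]) if len(themes) == 1 else None
        if (
            inner is not None
            and inner.id not in deleted
            and ev.type in _REG_TYPES
            and inner.type in _REG_TYPES
            and not any(base_role(r) == "Cause" for r, _ in inner.args)
        ):
            # collapse: move the cause one level down, drop this event
            events[inner.id] = replace(
                inner, args=inner.args + ((crole, ctarget),)
            )
            deleted.add(eid)
        else:
            # expand: wrap this event in a fresh regulation carrying the cause
            events[eid] = replace(ev, args=tuple(rest))
            trig_span = entities[ev.trigger_id].span
            tid = f"T{next_t}"
            next_t += 1
            entities[tid] = EntityAnnotation(tid, "Regulation", trig_span)
            new_id = f"E{next_e}"
            next_e += 1
            events[new_id] = EventAnnotation(
                new_id, "Regulation", tid,
                (("Theme", eid), (crole, ctarget)),
            )
            order.append(new_id)

    # span shifts on protein entities (keeps spans inside the text)
    n = len(doc.text)
    for tid, ent in list(entities.items()):
        if ent.type != "Protein" or not p.p_span_shift:
            continue
        if rng.random() < p.p_span_shift:
            delta = rng.choice([d for d in range(-p.span_shift_max,
                                                 p.span_shift_max + 1) if d])
            begin = min(max(0, ent.span.begin + delta), n - 1)
            end = min(max(begin + 1, ent.span.end + delta), n)
            entities[tid] = replace(ent, span=TextSpan(begin, end))

    # drop events whose trigger vanished and strip dangling argument targets
    surviving_events = [events[eid] for eid in order if eid not in deleted]
    live_ids = {e.id for e in surviving_events} | set(entities)
    surviving_events = [
        replace(ev, args=tuple((r, t) for r, t in ev.args if t in live_ids))
        for ev in surviving_events
    ]
    used_triggers = {e.trigger_id for e in surviving_events}
    used_targets = {t for e in surviving_events for _, t in e.args}
    kept_entities = [
        ent
        for ent in entities.values()  # insertion order: originals, then minted
        if ent.type == "Protein"
        or ent.id in used_triggers
        or ent.id in used_targets
    ]
    out = AstDocument(
        text=doc.text,
        entities=kept_entities,
        events=surviving_events,
        doc_ref=doc.doc_ref,
    )
    out.validate()
    return out
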