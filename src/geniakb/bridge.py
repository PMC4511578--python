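"""Conversion between event-centric (a*) and relation-centric (JSON) annotation.

An n-ary event is decomposed into one denotation (carrying the event id, the
trigger's span and the event type) plus n binary relations, one per argument,
directed participant -> event: a ``Theme`` argument becomes a ``themeOf``
relation whose subject is the participant and whose object is the event.
The inverse conversion reassembles events from event-typed denotations and
the relations pointing at them; grouping is given by the event denotation id
and never guessed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .pajson import Denotation, JsonDocument, RelationAnn
from .standoff import (
    AstDocument,
    EntityAnnotation,
    EventAnnotation,
    base_role,
)

__all__ = [
    "RoleMap",
    "DEFAULT_ROLE_MAP",
    "ConversionError",
    "events_to_relations",
    "relations_to_events",
    "GE_EVENT_TYPES",
]

#: Event-type vocabulary of the GE'13 schema (used to recognise event-typed
#: denotations on the reverse conversion).
GE_EVENT_TYPES = frozenset(
    {
        "Gene_expression",
        "Transcription",
        "Localization",
        "Binding",
        "Protein_catabolism",
        "Protein_modification",
        "Phosphorylation",
        "Ubiquitination",
        "Acetylation",
        "Deacetylation",
        "Regulation",
        "Positive_regulation",
        "Negative_regulation",
    }
)


class ConversionError(ValueError):
    """A role or predicate has no mapping in the configured RoleMap."""


@dataclass(frozen=True)
class RoleMap:
    """Injective table from argument role base names to relation predicates."""

    role_to_pred: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROLES)
    )

    def __post_init__(self) -> None:
        preds = list(self.role_to_pred.values())
        if len(set(preds)) != len(preds):
            raise ConversionError("role map is not injective")

    def pred(self, role: str) -> str:
        b = base_role(role)
        if b not in self.role_to_pred:
            raise ConversionError(f"no predicate mapped for role {role!r}")
        return self.role_to_pred[b]

    def role(self, pred: str) -> str:
        for r, p in self.role_to_pred.items():
            if p == pred:
                return r
        raise ConversionError(f"no role mapped for predicate {pred!r}")

    def has_pred(self, pred: str) -> bool:
        return pred in self.role_to_pred.values()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoleMap":
        table = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            role, pred = line.split("\t")
            table[role] = pred
        return cls(table)


DEFAULT_ROLES = (
    ("Theme", "themeOf"),
    ("Cause", "causeOf"),
    ("Site", "siteOf"),
    ("ToLoc", "toLocOf"),
    ("AtLoc", "atLocOf"),
    ("FromLoc", "fromLocOf"),
)

DEFAULT_ROLE_MAP = RoleMap(dict(DEFAULT_ROLES))


def events_to_relations(
    doc: AstDocument,
    rmap: RoleMap = DEFAULT_ROLE_MAP,
    *,
    keep_triggers: bool = False,
) -> JsonDocument:
    """Decompose events into denotations plus binary relations.

    Each entity becomes a denotation; each event becomes a denotation over
    its trigger's span typed with the event type, plus one relation per
    argument.  Trigger entities consumed by an event are omitted as
    standalone denotations (``keep_triggers=True`` restores them); when two
    events share a trigger, two event denotations with identical spans are
    emitted, one per event.  Relation ids are R1, R2, … in document order.
    """
    doc.validate()
    trigger_use = Counter(ev.trigger_id for ev in doc.events)
    emap = doc.entity_map()
    denotations: list[Denotation] = []
    for ent in doc.entities:
        if not keep_triggers and trigger_use[ent.id] >= 1:
            continue  # consumed as a trigger; the event denotation covers the span
        denotations.append(Denotation(ent.id, ent.span, ent.type))
    for ev in doc.events:
        trig = emap[ev.trigger_id]
        denotations.append(Denotation(ev.id, trig.span, ev.type))

    relations: list[RelationAnn] = []
    rid = 0
    for ev in doc.events:
        for role, target in ev.args:
            rid += 1
            relations.append(
                RelationAnn(f"R{rid}", rmap.pred(role), subj=target, obj=ev.id)
            )
    out = JsonDocument(
        text=doc.text,
        denotations=denotations,
        relations=relations,
        doc_ref=doc.doc_ref,
    )
    out.validate()
    return out


def relations_to_events(
    doc: JsonDocument,
    rmap: RoleMap = DEFAULT_ROLE_MAP,
    event_types: frozenset[str] | set[str] = GE_EVENT_TYPES,
    *,
    strict: bool = True,
) -> AstDocument:
    """Reassemble n-ary events from event-typed denotations and relations.

    Denotations whose concept is in ``event_types`` become events; a fresh
    trigger entity is minted over the same span (ids continue above the
    highest existing T index).  Relations targeting an event denotation
    become arguments, the role read off the inverse role map and suffixed on
    repetition (Theme, Theme2, …) in relation order.  Other denotations
    become entities; relations into non-event denotations are kept as opaque
    statements with a warning.  Unknown predicates raise in strict mode and
    pass through with a warning otherwise.
    """
    doc.validate()
    dmap = doc.denotation_map()
    is_event = {d.id: d.obj in event_types for d in doc.denotations}

    entities: list[EntityAnnotation] = []
    max_t = 0
    for d in doc.denotations:
        if d.id.startswith("T") and d.id[1:].isdigit():
            max_t = max(max_t, int(d.id[1:]))
        if not is_event[d.id]:
            entities.append(EntityAnnotation(d.id, d.obj, d.span))
    # entity ids may clash with minted trigger ids only above max_t, so start there
    next_t = max_t + 1

    events: list[EventAnnotation] = []
    args_for: dict[str, list[tuple[str, str]]] = {d.id: [] for d in doc.denotations}
    opaque: list[str] = []
    for r in doc.relations:
        if not rmap.has_pred(r.pred):
            if strict:
                raise ConversionError(
                    f"relation {r.id}: predicate {r.pred!r} not in role map"
                )
            warnings.warn(
                f"relation {r.id}: predicate {r.pred!r} not in role map; "
                "kept as opaque statement", stacklevel=2,
            )
            opaque.append(f"{r.id}\t{r.pred} Subj:{r.subj} Obj:{r.obj}")
            continue
        if is_event[r.obj]:
            args_for[r.obj].append((rmap.role(r.pred), r.subj))
        else:
            warnings.warn(
                f"relation {r.id}: object {r.obj} is not an event-typed "
                "denotation; kept as opaque statement", stacklevel=2,
            )
            opaque.append(f"{r.id}\t{r.pred} Subj:{r.subj} Obj:{r.obj}")

    # map old event denotation ids to fresh E ids in document order
    eid_map: dict[str, str] = {}
    for i, d in enumerate(
        (d for d in doc.denotations if is_event[d.id]), start=1
    ):
        eid_map[d.id] = f"E{i}"
    for d in doc.denotations:
        if not is_event[d.id]:
            continue
        trig_id = f"T{next_t}"
        next_t += 1
        entities.append(EntityAnnotation(trig_id, d.obj, d.span))
        role_counts: Counter[str] = Counter()
        args: list[tuple[str, str]] = []
        for role, target in args_for[d.id]:
            role_counts[role] += 1
            k = role_counts[role]
            label = role if k == 1 else f"{role}{k}"
            args.append((label, eid_map.get(target, target)))
        events.append(EventAnnotation(eid_map[d.id], d.obj, trig_id, tuple(args)))

    out = AstDocument(
        text=doc.text,
        entities=entities,
        events=events,
        doc_ref=doc.doc_ref,
        opaque_lines=opaque,
    )
    out.validate()
    return out


def event_signature(doc: AstDocument) -> set[tuple]:
    """Id-free semantic signature used to compare documents after round trips.

    An event is identified by (type, trigger span, multiset of
    (base role, resolved target)) where an entity target is its (type, span)
    and an event target is that event's own signature, recursively.
    """
    emap = doc.entity_map()
    vmap = doc.event_map()

    def resolve(target: str, seen: frozenset[str]) -> tuple:
        if target in emap:
            ent = emap[target]
            return ("entity", ent.type, ent.span.begin, ent.span.end)
        if target in seen:  # argument cycle; identify by id only
            return ("cycle", target)
        return sig(vmap[target], seen | {target})

    def sig(ev: EventAnnotation, seen: frozenset[str]) -> tuple:
        trig = emap[ev.trigger_id]
        args = tuple(
            sorted((base_role(r), resolve(t, seen)) for r, t in ev.args)
        )
        return ("event", ev.type, trig.span.begin, trig.span.end, args)

    return {sig(ev, frozenset({ev.id})) for ev in doc.events} | {
        ("entity", e.type, e.span.begin, e.span.end)
        for e in doc.entities
        if all(ev.trigger_id != e.id for ev in doc.events)
    }
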