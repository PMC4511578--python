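"""Reader/writer for the BioNLP shared-task a* standoff annotation format.

The a* format stores annotation separately from the text it describes and
references the text by caret offsets (positions between characters, counted
in Unicode code points, end-exclusive).  Each line is ``ID<TAB>statement``:

* ``T`` statements are entity annotations — space-delimited triples
  ``(entity-type, begin-offset, end-offset)``.
* ``E`` statements are event annotations — space-delimited, colon-joined
  pairs; the first pair is ``event-type:trigger-entity-id`` and the rest are
  ``role:target-id`` arguments.  Coordinated arguments carry number suffixes
  on the role (``Theme``, ``Theme2``, ``Theme3`` …).

Statements with other ID prefixes (``M``, ``R``, ``*`` — modifications,
coreference, equivalence) are preserved as opaque lines but not interpreted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "TextSpan",
    "EntityAnnotation",
    "EventAnnotation",
    "AstDocument",
    "DocRef",
    "StandoffParseError",
    "StandoffReferenceError",
    "StandoffBoundsError",
    "base_role",
    "parse_ast",
    "serialize_ast",
    "read_document",
    "write_document",
]


class StandoffParseError(ValueError):
    """A line does not follow the a* grammar."""


class StandoffReferenceError(ValueError):
    """An annotation references an id that does not resolve."""


class StandoffBoundsError(ValueError):
    """An entity span falls outside the document text."""


_ROLE_SUFFIX = re.compile(r"\d+$")
_ENTITY_ID = re.compile(r"^T[1-9]\d*$")
_EVENT_ID = re.compile(r"^E[1-9]\d*$")


def base_role(role: str) -> str:
    """Strip a coordination number suffix: ``Theme2`` -> ``Theme``.

    Idempotent; a bare role is returned unchanged.
    """
    return _ROLE_SUFFIX.sub("", role)


@dataclass(frozen=True, order=True)
class TextSpan:
    """Half-open character span ``[begin, end)`` in caret offsets."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.begin < self.end):
            raise StandoffBoundsError(
                f"invalid span [{self.begin}, {self.end}): need 0 <= begin < end"
            )


@dataclass(frozen=True)
class EntityAnnotation:
    id: str
    type: str
    span: TextSpan


@dataclass(frozen=True)
class EventAnnotation:
    id: str
    type: str
    trigger_id: str
    args: tuple[tuple[str, str], ...]  # (role, target id), order preserved


@dataclass(frozen=True)
class DocRef:
    """(source database, source id, division index) identifying a document."""

    sourcedb: str = "synthetic"
    sourceid: str = "0"
    divid: int = 0


@dataclass
class AstDocument:
    """An annotated document: text plus entity and event annotations."""

    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)
    doc_ref: DocRef = field(default_factory=DocRef)
    opaque_lines: list[str] = field(default_factory=list)

    def entity_map(self) -> dict[str, EntityAnnotation]:
        return {e.id: e for e in self.entities}

    def event_map(self) -> dict[str, EventAnnotation]:
        return {e.id: e for e in self.events}

    def validate(self) -> None:
        """Check id uniqueness, reference resolution, and span bounds."""
        ids: set[str] = set()
        for ann in (*self.entities, *self.events):
            if ann.id in ids:
                raise StandoffParseError(f"duplicate id {ann.id}")
            ids.add(ann.id)
        n = len(self.text)
        for ent in self.entities:
            if not _ENTITY_ID.match(ent.id):
                raise StandoffParseError(f"bad entity id {ent.id!r}")
            if ent.span.end > n:
                raise StandoffBoundsError(
                    f"{ent.id}: span [{ent.span.begin}, {ent.span.end}) exceeds "
                    f"text length {n}"
                )
        entity_ids = {e.id for e in self.entities}
        for ev in self.events:
            if not _EVENT_ID.match(ev.id):
                raise StandoffParseError(f"bad event id {ev.id!r}")
            if ev.trigger_id not in entity_ids:
                raise StandoffReferenceError(
                    f"{ev.id}: trigger {ev.trigger_id} does not resolve"
                )
            for role, target in ev.args:
                if target not in ids:
                    raise StandoffReferenceError(
                        f"{ev.id}: argument {role}:{target} does not resolve"
                    )


def parse_ast(lines: Iterable[str], text: str, doc_ref: DocRef | None = None) -> AstDocument:
    """Parse a* annotation lines against the document text.

    Raises :class:`StandoffParseError` (grammar), :class:`StandoffReferenceError`
    (dangling ids) or :class:`StandoffBoundsError` (span outside text); errors
    name the offending 1-based line number where applicable.
    """
    entities: list[EntityAnnotation] = []
    events: list[EventAnnotation] = []
    opaque: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if "\t" not in line:
            raise StandoffParseError(f"line {lineno}: missing tab delimiter: {line!r}")
        ann_id, statement = line.split("\t", 1)
        if _ENTITY_ID.match(ann_id):
            entities.append(_parse_entity(ann_id, statement, lineno))
        elif _EVENT_ID.match(ann_id):
            events.append(_parse_event(ann_id, statement, lineno))
        else:
            warnings.warn(
                f"line {lineno}: statement with unhandled id {ann_id!r} kept verbatim",
                stacklevel=2,
            )
            opaque.append(line)
    doc = AstDocument(
        text=text,
        entities=entities,
        events=events,
        doc_ref=doc_ref or DocRef(),
        opaque_lines=opaque,
    )
    doc.validate()
    return doc


def _parse_entity(ann_id: str, statement: str, lineno: int) -> EntityAnnotation:
    parts = statement.split(" ")
    if len(parts) != 3:
        raise StandoffParseError(
            f"line {lineno}: entity statement is not a space-delimited triple: "
            f"{statement!r}"
        )
    etype, begin_s, end_s = parts
    try:
        begin, end = int(begin_s), int(end_s)
    except ValueError:
        raise StandoffParseError(
            f"line {lineno}: non-integer offset in {statement!r}"
        ) from None
    try:
        span = TextSpan(begin, end)
    except StandoffBoundsError as exc:
        raise StandoffBoundsError(f"line {lineno}: {exc}") from None
    return EntityAnnotation(ann_id, etype, span)


def _parse_event(ann_id: str, statement: str, lineno: int) -> EventAnnotation:
    pairs = statement.split(" ")
    head = pairs[0]
    if ":" not in head:
        raise StandoffParseError(
            f"line {lineno}: event head {head!r} is not type:trigger-id"
        )
    etype, trigger_id = head.split(":", 1)
    args: list[tuple[str, str]] = []
    for pair in pairs[1:]:
        if not pair:
            continue
        if ":" not in pair:
            raise StandoffParseError(
                f"line {lineno}: event argument {pair!r} is not role:target-id"
            )
        role, target = pair.split(":", 1)
        args.append((role, target))
    return EventAnnotation(ann_id, etype, trigger_id, tuple(args))


def serialize_ast(doc: AstDocument) -> list[str]:
    """Serialize to a* lines (entities, then events, then opaque statements)."""
    doc.validate()
    lines = [
        f"{e.id}\t{e.type} {e.span.begin} {e.span.end}" for e in doc.entities
    ]
    for ev in doc.events:
        pairs = " ".join(f"{role}:{target}" for role, target in ev.args)
        head = f"{ev.type}:{ev.trigger_id}"
        lines.append(f"{ev.id}\t{head} {pairs}".rstrip())
    lines.extend(doc.opaque_lines)
    return lines


def read_document(txt_path: str | Path, ann_path: str | Path | None = None,
                  doc_ref: DocRef | None = None) -> AstDocument:
    """Read ``<doc>.txt`` plus standoff annotation.

    Two dialects are supported: single-stream ``<doc>.ann`` and the split
    ``<doc>.a1`` / ``<doc>.a2`` convention (entities vs. events + triggers).
    With ``ann_path=None`` the dialect is chosen by what exists next to the
    text file: ``.ann`` first, else ``.a1`` (+ ``.a2`` when present).
    """
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    lines: list[str] = []
    if ann_path is not None:
        lines = Path(ann_path).read_text(encoding="utf-8").splitlines()
    else:
        ann = txt_path.with_suffix(".ann")
        a1 = txt_path.with_suffix(".a1")
        if ann.exists():
            lines = ann.read_text(encoding="utf-8").splitlines()
        elif a1.exists():
            lines = a1.read_text(encoding="utf-8").splitlines()
            a2 = txt_path.with_suffix(".a2")
            if a2.exists():
                lines += a2.read_text(encoding="utf-8").splitlines()
        else:
            raise FileNotFoundError(f"no .ann or .a1 next to {txt_path}")
    if doc_ref is None:
        doc_ref = DocRef(sourcedb="file", sourceid=txt_path.stem, divid=0)
    return parse_ast(lines, text, doc_ref=doc_ref)


def write_document(doc: AstDocument, txt_path: str | Path,
                   ann_path: str | Path | None = None) -> None:
    """Write ``<doc>.txt`` and ``<doc>.ann`` (single-stream dialect)."""
    txt_path = Path(txt_path)
    txt_path.write_text(doc.text, encoding="utf-8")
    if ann_path is None:
        ann_path = txt_path.with_suffix(".ann")
    Path(ann_path).write_text(
        "".join(line + "\n" for line in serialize_ast(doc)), encoding="utf-8"
    )


def renumber(doc: AstDocument) -> AstDocument:
    """Return an equivalent document with ids renumbered T1.., E1.. in order.

    Used to compare documents up to id renaming.
    """
    emap = {e.id: f"T{i}" for i, e in enumerate(doc.entities, 1)}
    vmap = {e.id: f"E{i}" for i, e in enumerate(doc.events, 1)}
    both = {**emap, **vmap}
    return AstDocument(
        text=doc.text,
        entities=[replace(e, id=emap[e.id]) for e in doc.entities],
        events=[
            EventAnnotation(
                vmap[ev.id], ev.type, emap[ev.trigger_id],
                tuple((r, both[t]) for r, t in ev.args),
            )
            for ev in doc.events
        ],
        doc_ref=doc.doc_ref,
        opaque_lines=list(doc.opaque_lines),
    )
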