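"""Reader/writer for the relation-centric JSON annotation format.

A document is a JSON object with members ``text``, ``denotations`` and
``relations`` (plus ``sourcedb``/``sourceid``/``divid`` identifying the
source document).  A *denotation* states that a span of text denotes an
object of some concept; a *relation* states that two denoted objects stand
in a binary predicate (e.g. ``themeOf``, ``causeOf``).  All information is
carried by binary relations, so partial information — a lone causal link,
say — is representable without the rest of an event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .standoff import DocRef, TextSpan

__all__ = [
    "Denotation",
    "RelationAnn",
    "JsonDocument",
    "PajsonValidationError",
    "PajsonReferenceError",
    "parse_pajson",
    "serialize_pajson",
    "read_json_document",
    "write_json_document",
]


class PajsonValidationError(ValueError):
    """The JSON document violates the schema."""


class PajsonReferenceError(ValueError):
    """A relation endpoint does not resolve to a denotation."""


@dataclass(frozen=True)
class Denotation:
    id: str
    span: TextSpan
    obj: str


@dataclass(frozen=True)
class RelationAnn:
    id: str
    pred: str
    subj: str
    obj: str


@dataclass
class JsonDocument:
    text: str
    denotations: list[Denotation] = field(default_factory=list)
    relations: list[RelationAnn] = field(default_factory=list)
    doc_ref: DocRef = field(default_factory=DocRef)

    def denotation_map(self) -> dict[str, Denotation]:
        return {d.id: d for d in self.denotations}

    def validate(self) -> None:
        n = len(self.text)
        seen: set[str] = set()
        for d in self.denotations:
            if d.id in seen:
                raise PajsonValidationError(f"duplicate denotation id {d.id}")
            seen.add(d.id)
            if d.span.end > n:
                raise PajsonValidationError(
                    f"{d.id}: span [{d.span.begin}, {d.span.end}) exceeds text "
                    f"length {n}"
                )
        rseen: set[str] = set()
        for r in self.relations:
            if r.id in rseen:
                raise PajsonValidationError(f"duplicate relation id {r.id}")
            rseen.add(r.id)
            for endpoint in (r.subj, r.obj):
                if endpoint not in seen:
                    raise PajsonReferenceError(
                        f"relation {r.id}: endpoint {endpoint!r} does not resolve"
                    )
            if r.subj == r.obj:
                raise PajsonValidationError(
                    f"relation {r.id}: subject equals object ({r.subj})"
                )


_REQUIRED = ("text",)


def parse_pajson(data: str | bytes | dict) -> JsonDocument:
    """Parse and validate a JSON annotation document.

    ``data`` may be a serialized string/bytes or an already-decoded mapping.
    A missing ``relations`` member is read as an empty list.
    """
    if isinstance(data, (str, bytes)):
        try:
            obj = json.loads(data)
        except json.JSONDecodeError as exc:
            raise PajsonValidationError(f"not well-formed JSON: {exc}") from None
    else:
        obj = data
    if not isinstance(obj, dict):
        raise PajsonValidationError("document must be a JSON object")
    for member in _REQUIRED:
        if member not in obj:
            raise PajsonValidationError(f"missing required member {member!r}")
    if not isinstance(obj["text"], str):
        raise PajsonValidationError("member 'text' must be a string")

    denotations = []
    for i, d in enumerate(obj.get("denotations", [])):
        try:
            span = d["span"]
            denotations.append(
                Denotation(
                    id=str(d["id"]),
                    span=TextSpan(int(span["begin"]), int(span["end"])),
                    obj=str(d["obj"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PajsonValidationError(
                f"denotations[{i}] malformed: {exc}"
            ) from None
    relations = []
    for i, r in enumerate(obj.get("relations", [])):
        try:
            relations.append(
                RelationAnn(
                    id=str(r["id"]), pred=str(r["pred"]),
                    subj=str(r["subj"]), obj=str(r["obj"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise PajsonValidationError(f"relations[{i}] malformed: {exc}") from None

    doc = JsonDocument(
        text=obj["text"],
        denotations=denotations,
        relations=relations,
        doc_ref=DocRef(
            sourcedb=str(obj.get("sourcedb", "synthetic")),
            sourceid=str(obj.get("sourceid", "0")),
            divid=int(obj.get("divid", 0)),
        ),
    )
    doc.validate()
    return doc


def serialize_pajson(doc: JsonDocument, *, indent: int | None = 2) -> str:
    """Serialize with deterministic key order; ``relations`` always emitted."""
    doc.validate()
    obj = {
        "sourcedb": doc.doc_ref.sourcedb,
        "sourceid": doc.doc_ref.sourceid,
        "divid": doc.doc_ref.divid,
        "text": doc.text,
        "denotations": [
            {
                "id": d.id,
                "span": {"begin": d.span.begin, "end": d.span.end},
                "obj": d.obj,
            }
            for d in doc.denotations
        ],
        "relations": [
            {"id": r.id, "pred": r.pred, "subj": r.subj, "obj": r.obj}
            for r in doc.relations
        ],
    }
    return json.dumps(obj, ensure_ascii=False, indent=indent)


def read_json_document(path: str | Path) -> JsonDocument:
    return parse_pajson(Path(path).read_text(encoding="utf-8"))


def write_json_document(doc: JsonDocument, path: str | Path) -> None:
    Path(path).write_text(serialize_pajson(doc) + "\n", encoding="utf-8")
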