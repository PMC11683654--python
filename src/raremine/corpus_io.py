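"""Annotated-corpus I/O and dataset preparation.

Corpora follow the BRAT standoff convention: a plain-text ``.txt`` file plus
an ``.ann`` file of entity records (``T<n>\\t<type> <start> <end>\\t<surface>``)
and binary relation records (``R<n>\\t<type> Arg1:T<i> Arg2:T<j>``).  Character
offsets are 0-based half-open.

The entity type system is {rare_disease, disease, symptom_and_sign, anaphor};
source corpora that still carry separate Symptom and Sign labels are folded
into ``symptom_and_sign`` by :func:`merge_symptom_sign`.  Relation types are
{produces, increases_risk_of, is_a, is_acron, is_synon, anaphora}; the
antecedent of an anaphora relation must be a rare disease.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

ENTITY_TYPES = ("rare_disease", "disease", "symptom_and_sign", "anaphor")
RELATION_TYPES = ("produces", "increases_risk_of", "is_a", "is_acron", "is_synon", "anaphora")

#: raw labels accepted on input before merging (case-insensitive)
_PRE_MERGE_TYPES = frozenset(ENTITY_TYPES) | {"symptom", "sign"}


@dataclass(frozen=True)
class EntityMention:
    """One entity occurrence in a document.

    ``span`` is optional: gold annotations always carry offsets, while
    predictions may be name-only.  When present, ``text[start:end]`` must
    reproduce ``surface``.
    """

    surface: str
    entity_type: str
    span: tuple[int, int] | None = None
    mention_id: str = ""


@dataclass(frozen=True)
class RelationInstance:
    """A typed, directed relation; refs are mention ids when spans exist,
    surface strings otherwise."""

    relation_type: str
    subject_ref: str
    object_ref: str


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    def mention_by_id(self, mention_id: str) -> EntityMention | None:
        for m in self.entities:
            if m.mention_id == mention_id:
                return m
        return None


@dataclass
class DatasetSplit:
    train: list[AnnotatedDocument]
    validation: list[AnnotatedDocument]
    test: list[AnnotatedDocument]
    ratios: tuple[float, float, float]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


class StandoffError(ValueError):
    """A malformed or inconsistent standoff record."""


def _read_text(stream: str | Path | TextIO) -> str:
    if isinstance(stream, (str, Path)):
        return Path(stream).read_text(encoding="utf-8")
    return stream.read()


def read_standoff(
    text_stream: str | Path | TextIO,
    ann_stream: str | Path | TextIO,
    doc_id: str = "",
) -> AnnotatedDocument:
    """Materialize a BRAT ``.txt`` + ``.ann`` pair into an AnnotatedDocument.

    Every T record's offsets are validated against the text; unknown type
    tags and dangling relation arguments raise :class:`StandoffError` naming
    the offending record.
    """
    text = _read_text(text_stream)
    ann = _read_text(ann_stream)
    entities: list[EntityMention] = []
    relations: list[RelationInstance] = []
    mention_ids: set[str] = set()
    for raw in ann.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise StandoffError(f"{tag}: entity record needs 3 tab fields: {line!r}")
            type_and_span = fields[1].split(" ")
            if len(type_and_span) != 3:
                raise StandoffError(f"{tag}: expected '<type> <start> <end>': {fields[1]!r}")
            etype, start_s, end_s = type_and_span
            canonical = etype.lower()
            if canonical not in _PRE_MERGE_TYPES:
                raise StandoffError(f"{tag}: unknown entity type {etype!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise StandoffError(f"{tag}: non-integer offsets {fields[1]!r}") from exc
            surface = fields[2]
            if not (0 <= start < end <= len(text)) or text[start:end] != surface:
                raise StandoffError(
                    f"{tag}: span {start}:{end} does not reproduce surface "
                    f"{surface!r} (text has {text[start:end]!r})"
                )
            entities.append(EntityMention(surface, canonical, (start, end), tag))
            mention_ids.add(tag)
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise StandoffError(f"{tag}: relation record needs 2 tab fields: {line!r}")
            parts = fields[1].split(" ")
            if len(parts) != 3:
                raise StandoffError(f"{tag}: expected '<type> Arg1:T.. Arg2:T..': {fields[1]!r}")
            rtype = parts[0].lower()
            if rtype not in RELATION_TYPES:
                raise StandoffError(f"{tag}: unknown relation type {parts[0]!r}")
            refs = []
            for argpart in parts[1:]:
                if ":" not in argpart:
                    raise StandoffError(f"{tag}: malformed argument {argpart!r}")
                refs.append(argpart.split(":", 1)[1])
            relations.append(RelationInstance(rtype, refs[0], refs[1]))
        else:
            raise StandoffError(f"unsupported standoff record {line!r}")
    for rel in relations:
        for ref in (rel.subject_ref, rel.object_ref):
            if ref not in mention_ids:
                raise StandoffError(
                    f"relation {rel.relation_type} references unknown mention {ref!r}"
                )
    return AnnotatedDocument(doc_id=doc_id, text=text, entities=entities, relations=relations)


def write_standoff(doc: AnnotatedDocument, text_out: TextIO, ann_out: TextIO) -> None:
    """Inverse of :func:`read_standoff` for span-bearing documents."""
    text_out.write(doc.text)
    for m in doc.entities:
        if m.span is None:
            raise StandoffError(f"mention {m.mention_id or m.surface!r} has no span")
        ann_out.write(f"{m.mention_id}\t{m.entity_type} {m.span[0]} {m.span[1]}\t{m.surface}\n")
    for i, r in enumerate(doc.relations, start=1):
        ann_out.write(f"R{i}\t{r.relation_type} Arg1:{r.subject_ref} Arg2:{r.object_ref}\n")


def merge_symptom_sign(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Fold the separate Symptom and Sign labels into ``symptom_and_sign``.

    Idempotent; every other field is untouched.
    """
    merged = [
        replace(m, entity_type="symptom_and_sign")
        if m.entity_type in ("symptom", "sign")
        else m
        for m in doc.entities
    ]
    return AnnotatedDocument(doc.doc_id, doc.text, merged, list(doc.relations))


def largest_remainder_apportionment(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion ``n`` items across parts proportionally to ``ratios``,
    assigning leftovers by largest fractional remainder (earlier part wins
    ties)."""
    total = float(sum(ratios))
    if total <= 0:
        raise ValueError("ratios must have a positive sum")
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    leftovers = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:leftovers]:
        sizes[i] += 1
    return sizes


def split_dataset(
    docs: Sequence[AnnotatedDocument],
    ratios: tuple[float, float, float] = (6, 2, 2),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded shuffle followed by a contiguous train/validation/test partition.

    Sizes follow largest-remainder apportionment of ``len(docs)`` across the
    ratio, so 1040 documents at 6:2:2 yield 624/208/208.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be positive, got {ratios}")
    if len(docs) < len(ratios):
        raise ValueError(f"need at least {len(ratios)} documents, got {len(docs)}")
    shuffled = list(docs)
    random.Random(seed).shuffle(shuffled)
    a, b, c = largest_remainder_apportionment(len(docs), ratios)
    return DatasetSplit(
        train=shuffled[:a],
        validation=shuffled[a : a + b],
        test=shuffled[a + b :],
        ratios=tuple(ratios),
    )


# ---------------------------------------------------------------------------
# extraction-result JSON

def _mention_to_json(m: EntityMention) -> dict:
    record: dict = {"id": m.mention_id, "text": m.surface, "type": m.entity_type}
    if m.span is not None:
        record["start"], record["end"] = m.span
    return record


def _mention_from_json(record: dict) -> EntityMention:
    span = (record["start"], record["end"]) if "start" in record else None
    return EntityMention(record["text"], record["type"], span, record.get("id", ""))


def write_extraction(results: Iterable, out_stream: TextIO) -> None:
    """Serialize extraction results (one JSON document per input) loss-free.

    ``results`` are :class:`~raremine.pipeline.ExtractionResult` objects or
    anything exposing ``doc_id``, ``entities``, ``relations`` and optionally
    ``provenance``.
    """
    payload = []
    for res in results:
        payload.append(
            {
                "doc_id": res.doc_id,
                "entities": [_mention_to_json(m) for m in res.entities],
                "relations": [
                    {"type": r.relation_type, "subject": r.subject_ref, "object": r.object_ref}
                    for r in res.relations
                ],
                "provenance": getattr(res, "provenance", {}) or {},
            }
        )
    json.dump(payload, out_stream, indent=1)


def read_extraction(in_stream: str | Path | TextIO) -> list:
    """Re-read :func:`write_extraction` output into ExtractionResult objects."""
    from .pipeline import ExtractionResult  # local import avoids a cycle

    raw = _read_text(in_stream)
    out = []
    for record in json.loads(raw):
        out.append(
            ExtractionResult(
                doc_id=record["doc_id"],
                entities=[_mention_from_json(e) for e in record["entities"]],
                relations=[
                    RelationInstance(r["type"], r["subject"], r["object"])
                    for r in record["relations"]
                ],
                provenance=record.get("provenance", {}),
            )
        )
    return out
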