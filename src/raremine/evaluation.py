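"""Scoring of predicted entities and relations against gold annotations.

Scoring is occurrence-level multiset matching per document: a predicted
mention pairs with an unmatched gold mention of the same document when their
normalized names and types are equal, and each gold occurrence can satisfy
at most one prediction (replicated entities therefore count as many times as
they occur).  A predicted relation matches an unmatched gold relation with
equal (normalized subject name, relation type, normalized object name),
independently of whether the endpoint entities were themselves scored
correct.  Precision, recall and F1 are micro-averaged from pooled counts,
per type and overall; the headline overall F1 is the arithmetic mean of the
entity-overall and relation-overall F1 (and overall P and R are the means of
the corresponding overall P and R).

Confusion matrices exclude replicated entities: per document, names are
deduplicated to a type-level set before counting.  "Error" on the predicted
axis collects falsely extracted items; "Error" on the true axis collects
gold items that were not extracted.

All internal math is unrounded; percentages are rounded half-up to one
decimal at report time only.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import (
    ENTITY_TYPES,
    RELATION_TYPES,
    AnnotatedDocument,
    EntityMention,
    RelationInstance,
)
from .normalize import normalize_name
from .pipeline import ExtractionResult

ERROR_LABEL = "Error"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 44.95 -> 45.0, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 on the percent scale, with the raw pooled counts."""

    precision: float
    recall: float
    f1: float
    matched: int = 0
    n_pred: int = 0
    n_gold: int = 0

    @staticmethod
    def from_counts(matched: int, n_pred: int, n_gold: int) -> "PRF":
        p = 100.0 * matched / n_pred if n_pred else 0.0
        r = 100.0 * matched / n_gold if n_gold else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        return PRF(p, r, f1, matched, n_pred, n_gold)


@dataclass
class MetricsReport:
    per_entity_type: dict[str, PRF] = field(default_factory=dict)
    entity_overall: PRF = PRF(0.0, 0.0, 0.0)
    per_relation_type: dict[str, PRF] = field(default_factory=dict)
    relation_overall: PRF = PRF(0.0, 0.0, 0.0)
    overall: PRF = PRF(0.0, 0.0, 0.0)
    flags: list[str] = field(default_factory=list)


@dataclass
class ConfusionMatrix:
    """Square count grid over ``labels`` (rows = true, columns = predicted),
    with the trailing Error label for unmatched items on either axis."""

    labels: list[str]
    counts: np.ndarray

    def cell(self, true_label: str, pred_label: str) -> int:
        return int(self.counts[self.labels.index(true_label), self.labels.index(pred_label)])

    def row_sum(self, true_label: str) -> int:
        return int(self.counts[self.labels.index(true_label)].sum())


# ---------------------------------------------------------------------------
# multiset matching

def _as_doc_map(items, kind: str) -> dict[str, list]:
    """Accept a flat list (one document) or a doc_id -> list mapping."""
    if isinstance(items, Mapping):
        return dict(items)
    return {"": list(items)}


def _entity_key(m: EntityMention) -> tuple[str, str]:
    return (normalize_name(m.surface), m.entity_type)


def _relation_key(r: RelationInstance, doc=None) -> tuple[str, str, str]:
    return (
        normalize_name(_deref(r.subject_ref, doc)),
        r.relation_type,
        normalize_name(_deref(r.object_ref, doc)),
    )


def _deref(ref: str, doc: AnnotatedDocument | None) -> str:
    """Resolve a mention-id ref to its surface when a document is supplied."""
    if doc is not None:
        m = doc.mention_by_id(ref)
        if m is not None:
            return m.surface
    return ref


def _score_keyed(
    pred_by_doc: dict[str, list],
    gold_by_doc: dict[str, list],
    key_of,
    type_of,
    all_types: Sequence[str],
) -> tuple[dict[str, PRF], PRF]:
    """Pooled greedy multiset matching by equality key.

    With equality-keyed pairing the greedy match per document equals the
    optimal bipartite matching (min of the two multiplicities per key), so
    order cannot change totals.
    """
    matched: Counter = Counter()
    n_pred: Counter = Counter()
    n_gold: Counter = Counter()
    for doc_id in set(pred_by_doc) | set(gold_by_doc):
        pred_keys = Counter(key_of(x, doc_id) for x in pred_by_doc.get(doc_id, []))
        gold_keys = Counter(key_of(x, doc_id) for x in gold_by_doc.get(doc_id, []))
        for key, count in pred_keys.items():
            n_pred[type_of(key)] += count
            matched[type_of(key)] += min(count, gold_keys.get(key, 0))
        for key, count in gold_keys.items():
            n_gold[type_of(key)] += count
    per_type = {
        t: PRF.from_counts(matched[t], n_pred[t], n_gold[t]) for t in all_types
    }
    overall = PRF.from_counts(
        sum(matched.values()), sum(n_pred.values()), sum(n_gold.values())
    )
    return per_type, overall


def score_entities(pred, gold) -> tuple[dict[str, PRF], PRF]:
    """Per-type and micro-overall P/R/F1 for entity mentions.

    ``pred``/``gold`` are flat mention lists (one document) or doc_id ->
    mention-list mappings.  Pairing requires equal (normalized name, type);
    a name predicted with the wrong type is both a miss for the gold type
    and a false positive for the predicted type.
    """
    return _score_keyed(
        _as_doc_map(pred, "entities"),
        _as_doc_map(gold, "entities"),
        lambda m, _doc: _entity_key(m),
        lambda key: key[1],
        ENTITY_TYPES,
    )


def score_relations(pred, gold, gold_docs: dict[str, AnnotatedDocument] | None = None):
    """Per-type and micro-overall P/R/F1 for relations.

    Matching is by (normalized subject name, type, normalized object name);
    ``gold_docs`` lets mention-id refs in gold relations resolve to surfaces.
    """
    docs = gold_docs or {}
    return _score_keyed(
        _as_doc_map(pred, "relations"),
        _as_doc_map(gold, "relations"),
        lambda r, doc_id: _relation_key(r, docs.get(doc_id)),
        lambda key: key[1],
        RELATION_TYPES,
    )


def overall_score(entity_f1: float, relation_f1: float) -> float:
    """The headline metric: arithmetic mean of entity and relation F1,
    reported to one decimal, round-half-up."""
    mean = (Decimal(str(entity_f1)) + Decimal(str(relation_f1))) / 2
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def evaluate_corpus(
    predictions: Iterable[ExtractionResult],
    gold_docs: Iterable[AnnotatedDocument],
) -> MetricsReport:
    """Score a prediction set against its gold corpus into a full report."""
    preds = list(predictions)
    golds = list(gold_docs)
    pred_entities = {p.doc_id: p.entities for p in preds}
    gold_entities = {g.doc_id: g.entities for g in golds}
    pred_relations = {p.doc_id: p.relations for p in preds}
    gold_relations = {g.doc_id: g.relations for g in golds}
    docs_by_id = {g.doc_id: g for g in golds}

    per_entity, entity_overall = score_entities(pred_entities, gold_entities)
    per_relation, relation_overall = score_relations(
        pred_relations, gold_relations, docs_by_id
    )
    overall = PRF(
        precision=(entity_overall.precision + relation_overall.precision) / 2,
        recall=(entity_overall.recall + relation_overall.recall) / 2,
        f1=(entity_overall.f1 + relation_overall.f1) / 2,
    )
    flags = []
    if entity_overall.n_pred == 0:
        flags.append("no predicted entities: entity precision undefined, reported as 0")
    if relation_overall.n_pred == 0:
        flags.append("no predicted relations: relation precision undefined, reported as 0")
    return MetricsReport(
        per_entity_type=per_entity,
        entity_overall=entity_overall,
        per_relation_type=per_relation,
        relation_overall=relation_overall,
        overall=overall,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# confusion matrices

def _dedup_entity_map(mentions: Iterable[EntityMention]) -> dict[str, str]:
    out: dict[str, str] = {}
    for m in mentions:
        out.setdefault(normalize_name(m.surface), m.entity_type)
    return out


def _dedup_relation_map(relations, doc) -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    for r in relations:
        key = (normalize_name(_deref(r.subject_ref, doc)), normalize_name(_deref(r.object_ref, doc)))
        out.setdefault(key, r.relation_type)
    return out


def _fill_matrix(labels, gold_maps, pred_maps) -> ConfusionMatrix:
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for gold_map, pred_map in zip(gold_maps, pred_maps):
        for key, true_type in gold_map.items():
            pred_type = pred_map.get(key, ERROR_LABEL)
            counts[index[true_type], index.get(pred_type, index[ERROR_LABEL])] += 1
        for key, pred_type in pred_map.items():
            if key not in gold_map:
                counts[index[ERROR_LABEL], index.get(pred_type, index[ERROR_LABEL])] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts)


def confusion_matrices(
    predictions: Iterable[ExtractionResult],
    gold_docs: Iterable[AnnotatedDocument],
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Error-augmented entity and relation confusion matrices.

    Replicated items are excluded: per document, entities reduce to a set of
    normalized names (first-seen type) and relations to a set of
    (subject, object) pairs, before counting.
    """
    preds = {p.doc_id: p for p in predictions}
    golds = list(gold_docs)
    entity_labels = list(ENTITY_TYPES) + [ERROR_LABEL]
    relation_labels = list(RELATION_TYPES) + [ERROR_LABEL]
    gold_e, pred_e, gold_r, pred_r = [], [], [], []
    for g in golds:
        p = preds.get(g.doc_id, ExtractionResult(doc_id=g.doc_id))
        gold_e.append(_dedup_entity_map(g.entities))
        pred_e.append(_dedup_entity_map(p.entities))
        gold_r.append(_dedup_relation_map(g.relations, g))
        pred_r.append(_dedup_relation_map(p.relations, None))
    return (
        _fill_matrix(entity_labels, gold_e, pred_e),
        _fill_matrix(relation_labels, gold_r, pred_r),
    )


# ---------------------------------------------------------------------------
# report rendering

def _prf_row(name: str, prf: PRF, reference: PRF | None = None) -> list[str]:
    row = [
        name,
        f"{round_half_up(prf.precision):.1f}",
        f"{round_half_up(prf.recall):.1f}",
        f"{round_half_up(prf.f1):.1f}",
    ]
    if reference is not None:
        delta = round_half_up(prf.f1) - round_half_up(reference.f1)
        row.append(f"{round_half_up(delta):+.1f}")
    return row


def _report_rows(metrics: MetricsReport, reference: MetricsReport | None):
    ref = reference
    rows = [["type", "precision", "recall", "f1"] + (["∇f1"] if ref else [])]
    for t, prf in metrics.per_entity_type.items():
        rows.append(_prf_row(t, prf, ref.per_entity_type.get(t) if ref else None))
    rows.append(_prf_row("entity_overall", metrics.entity_overall, ref.entity_overall if ref else None))
    for t, prf in metrics.per_relation_type.items():
        rows.append(_prf_row(t, prf, ref.per_relation_type.get(t) if ref else None))
    rows.append(
        _prf_row("relation_overall", metrics.relation_overall, ref.relation_overall if ref else None)
    )
    rows.append(_prf_row("overall", metrics.overall, ref.overall if ref else None))
    return rows


def report(
    metrics: MetricsReport,
    fmt: str = "text_table",
    reference: MetricsReport | None = None,
) -> str:
    """Render per-type rows then overall rows with one-decimal percentages;
    with a ``reference`` report, delta columns are added (negative values
    carry a minus sign)."""
    if fmt == "text_table":
        rows = _report_rows(metrics, reference)
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows]
        if metrics.flags:
            lines.extend(f"# {flag}" for flag in metrics.flags)
        return "\n".join(lines)
    if fmt == "json":
        return json.dumps(metrics_to_dict(metrics), indent=1)
    if fmt == "csv":
        rows = _report_rows(metrics, reference)
        return "\n".join(",".join(row) for row in rows)
    raise ValueError(f"unknown report format {fmt!r}")


def metrics_to_dict(metrics: MetricsReport) -> dict:
    def prf_dict(prf: PRF) -> dict:
        return {
            "precision": prf.precision, "recall": prf.recall, "f1": prf.f1,
            "matched": prf.matched, "n_pred": prf.n_pred, "n_gold": prf.n_gold,
        }

    return {
        "per_entity_type": {t: prf_dict(p) for t, p in metrics.per_entity_type.items()},
        "entity_overall": prf_dict(metrics.entity_overall),
        "per_relation_type": {t: prf_dict(p) for t, p in metrics.per_relation_type.items()},
        "relation_overall": prf_dict(metrics.relation_overall),
        "overall": prf_dict(metrics.overall),
        "flags": list(metrics.flags),
    }


def metrics_from_dict(payload: dict) -> MetricsReport:
    def prf(d: dict) -> PRF:
        return PRF(
            d["precision"], d["recall"], d["f1"],
            d.get("matched", 0), d.get("n_pred", 0), d.get("n_gold", 0),
        )

    return MetricsReport(
        per_entity_type={t: prf(p) for t, p in payload["per_entity_type"].items()},
        entity_overall=prf(payload["entity_overall"]),
        per_relation_type={t: prf(p) for t, p in payload["per_relation_type"].items()},
        relation_overall=prf(payload["relation_overall"]),
        overall=prf(payload["overall"]),
        flags=list(payload.get("flags", [])),
    )
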