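"""End-to-end extraction: segmentation, three-step entity extraction,
relation extraction with ontology triples, bridge-window relation recovery,
and entity calibration.

Entity extraction is staged chain-of-thought style: (1) dictionary string
matching with negation flags, (2) a model pass asking for additional terms
and anaphors, (3) a model pass assigning one of the four entity types to each
candidate, with rare-disease knowledge injected for candidates that hit the
rare-disease lexicon.  The step-3 output is authoritative — dictionary hits
are hints, not guarantees.  Relations are extracted per segment over the
extracted entities, then re-extracted over bridge windows that straddle
segment boundaries; duplicates are collapsed by (subject, type, object).
Finally, calibration removes entities participating in no relation (rule),
asks the model to confirm the retained list (llm), or both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import ENTITY_TYPES, RELATION_TYPES, EntityMention, RelationInstance
from .llm_runtime import Backend, BackendConfig, complete, parse_json_payload
from .normalize import normalize_name
from .ontology_kb import KnowledgeBase, lookup_associations, lookup_rare_disease
from .preprocess import (
    DEFAULT_BRIDGE_TOKENS,
    DEFAULT_SEGMENT_TOKENS,
    Segment,
    bridge_windows,
    segment_document,
)
from .prompting import (
    AblationToggles,
    Exemplar,
    render_calibration_prompt,
    render_entity_prompt,
    render_extract_more_terms,
    render_relation_prompt,
)
from .term_matcher import NegationLexicon, annotate_negation, load_negation_lexicon, match_terms

logger = logging.getLogger(__name__)

CALIBRATION_MODES = ("llm", "rule", "both")


@dataclass
class ExtractionResult:
    """Entities and relations extracted from one document, with per-item
    provenance tags (parallel to the entity/relation lists)."""

    doc_id: str
    entities: list[EntityMention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    toggles: AblationToggles = field(default_factory=AblationToggles)
    max_segment_tokens: int = DEFAULT_SEGMENT_TOKENS
    bridge_tokens: int = DEFAULT_BRIDGE_TOKENS
    bridge_enabled: bool = True
    backend: BackendConfig = field(default_factory=BackendConfig)
    calibration_mode: str = "both"
    exemplar_seed: int = 0
    entity_exemplars: list[Exemplar] = field(default_factory=list)
    relation_exemplars: list[Exemplar] = field(default_factory=list)
    negation: NegationLexicon | None = None
    prompts_dir: str | None = None
    prompt_budget_tokens: int = 1000

    def __post_init__(self) -> None:
        if self.calibration_mode not in CALIBRATION_MODES:
            raise ValueError(
                f"calibration_mode must be one of {CALIBRATION_MODES}, "
                f"got {self.calibration_mode!r}"
            )

    @property
    def tokenizer_spec(self) -> str:
        return self.backend.tokenizer_spec


def _render_kwargs(config: PipelineConfig) -> dict:
    return {
        "budget_tokens": config.prompt_budget_tokens,
        "tokenizer_spec": config.tokenizer_spec,
        "prompts_dir": config.prompts_dir,
    }


def _segment_mention(record: dict, segment: Segment, index: int) -> EntityMention | None:
    """Turn one model entity record into a document-coordinate mention.

    Offsets in model output are relative to the passage shown; they are
    shifted by the segment origin and dropped if they fail to reproduce the
    surface.
    """
    text = record.get("text")
    etype = record.get("type")
    if not isinstance(text, str) or not text:
        return None
    span = None
    if isinstance(record.get("start"), int) and isinstance(record.get("end"), int):
        start = record["start"] + segment.char_start
        end = record["end"] + segment.char_start
        if 0 <= record["start"] < record["end"] and segment.text[record["start"] : record["end"]] == text:
            span = (start, end)
    return EntityMention(
        surface=text,
        entity_type=str(etype),
        span=span,
        mention_id=f"{segment.doc_id}:s{segment.seg_index}:e{index}",
    )


def extract_entities(
    segment: Segment,
    kb: KnowledgeBase,
    backend: Backend,
    config: PipelineConfig,
) -> tuple[list[EntityMention], list[str]]:
    """Run the three entity-extraction steps on one segment.

    Returns (mentions, provenance tags).  Model outputs typed outside the
    entity type system are dropped with a warning.
    """
    neg = config.negation or load_negation_lexicon()
    matches = annotate_negation(match_terms(segment.text, kb.concept_lexicon), segment.text, neg)

    prompt = render_extract_more_terms(segment, matches, config.toggles, **_render_kwargs(config))
    payload = parse_json_payload(
        complete(config.backend, prompt, backend).response_text,
        list_keys=("terms", "anaphors"),
    )
    extra_terms = [str(t) for t in payload["terms"]]
    anaphors = [str(a) for a in payload["anaphors"]]

    candidates: list[dict] = [
        {"text": m.surface, "negated": m.negated} for m in matches
    ]
    seen = {normalize_name(m.surface) for m in matches}
    for term in extra_terms:
        if normalize_name(term) not in seen:
            seen.add(normalize_name(term))
            candidates.append({"text": term})
    rd_knowledge = []
    rd_seen = set()
    for cand in candidates:
        concept = lookup_rare_disease(kb, cand["text"])
        if concept is not None and concept.concept_id not in rd_seen:
            rd_seen.add(concept.concept_id)
            rd_knowledge.append(concept)

    prompt = render_entity_prompt(
        segment, candidates, anaphors, config.entity_exemplars, rd_knowledge,
        config.toggles, **_render_kwargs(config),
    )
    payload = parse_json_payload(
        complete(config.backend, prompt, backend).response_text, list_keys=("entities",)
    )
    mentions: list[EntityMention] = []
    tags: list[str] = []
    for i, record in enumerate(payload["entities"]):
        if not isinstance(record, dict):
            continue
        mention = _segment_mention(record, segment, i)
        if mention is None:
            continue
        if mention.entity_type not in ENTITY_TYPES:
            logger.warning(
                "dropping entity %r with type %r outside the type system",
                mention.surface, mention.entity_type,
            )
            continue
        mentions.append(mention)
        tags.append(f"llm_entities/segment:{segment.seg_index}")
    return mentions, tags


def extract_relations(
    segment: Segment,
    entities: list[EntityMention],
    kb: KnowledgeBase,
    backend: Backend,
    config: PipelineConfig,
) -> list[RelationInstance]:
    """Relation extraction over one segment (or bridge window).

    Model relations are filtered: both endpoints must be among the provided
    entities, the type must be in the relation type system, and an anaphora
    relation must point at a rare-disease antecedent.
    """
    associations = []
    assoc_seen = set()
    for m in entities:
        if m.entity_type == "rare_disease":
            key = normalize_name(m.surface)
            if key not in assoc_seen:
                assoc_seen.add(key)
                associations.extend(lookup_associations(kb, m.surface))
    prompt = render_relation_prompt(
        segment, entities, associations if config.toggles.use_knowledge else [],
        config.relation_exemplars, config.toggles, **_render_kwargs(config),
    )
    payload = parse_json_payload(
        complete(config.backend, prompt, backend).response_text, list_keys=("relations",)
    )
    types_by_name: dict[str, set[str]] = {}
    for m in entities:
        types_by_name.setdefault(normalize_name(m.surface), set()).add(m.entity_type)
    relations: list[RelationInstance] = []
    for record in payload["relations"]:
        if not isinstance(record, dict):
            continue
        rtype = record.get("type")
        subj = record.get("subject")
        obj = record.get("object")
        if rtype not in RELATION_TYPES:
            logger.warning("dropping relation with type %r outside the type system", rtype)
            continue
        if not isinstance(subj, str) or not isinstance(obj, str):
            continue
        subj_types = types_by_name.get(normalize_name(subj))
        obj_types = types_by_name.get(normalize_name(obj))
        if not subj_types or not obj_types:
            logger.warning(
                "dropping relation %s(%r, %r): endpoint not among extracted entities",
                rtype, subj, obj,
            )
            continue
        if rtype == "anaphora" and "rare_disease" not in obj_types:
            logger.warning(
                "dropping anaphora relation with non-rare-disease antecedent %r", obj
            )
            continue
        relations.append(RelationInstance(rtype, subj, obj))
    return relations


def calibrate(
    entities: list[EntityMention],
    relations: list[RelationInstance],
    backend: Backend,
    mode: str = "both",
    config: PipelineConfig | None = None,
    doc_id: str = "",
) -> tuple[list[EntityMention], list[RelationInstance]]:
    """Filter entities that are likely irrelevant.

    ``rule`` drops entities participating in zero relations; ``llm`` asks the
    model for the retained list (constrained to a subset of the input);
    ``both`` applies the rule first, then the model on the survivors.
    Relations referencing a dropped entity are removed.  Output entities are
    always a subset of the input.
    """
    if mode not in CALIBRATION_MODES:
        raise ValueError(f"unknown calibration mode {mode!r}")
    config = config or PipelineConfig()
    kept = list(entities)
    if mode in ("rule", "both"):
        related = set()
        for rel in relations:
            related.add(normalize_name(rel.subject_ref))
            related.add(normalize_name(rel.object_ref))
        kept = [m for m in kept if normalize_name(m.surface) in related]
    if mode in ("llm", "both"):
        prompt = render_calibration_prompt(
            kept, relations, doc_id, config.toggles, **_render_kwargs(config)
        )
        payload = parse_json_payload(
            complete(config.backend, prompt, backend).response_text, list_keys=("entities",)
        )
        retained = {normalize_name(str(name)) for name in payload["entities"]}
        kept = [m for m in kept if normalize_name(m.surface) in retained]
    surviving = {normalize_name(m.surface) for m in kept}
    relations = [
        r
        for r in relations
        if normalize_name(r.subject_ref) in surviving
        and normalize_name(r.object_ref) in surviving
    ]
    return kept, relations


def _relation_key(rel: RelationInstance) -> tuple[str, str, str]:
    return (normalize_name(rel.subject_ref), rel.relation_type, normalize_name(rel.object_ref))


def run_document(
    doc_text: str,
    doc_id: str,
    kb: KnowledgeBase,
    config: PipelineConfig,
    backend: Backend,
) -> ExtractionResult:
    """Full pipeline over one document.

    Segments the text, extracts entities and relations per segment, re-runs
    relation extraction over bridge windows at segment boundaries (entity
    occurrences flanking each boundary are fed in; new relations are merged,
    duplicates collapse by (subject, type, object)), then calibrates.
    """
    segments = segment_document(
        doc_text, config.max_segment_tokens, doc_id=doc_id,
        tokenizer_spec=config.tokenizer_spec,
    )
    all_entities: list[EntityMention] = []
    entity_tags: list[str] = []
    entities_by_segment: dict[int, list[EntityMention]] = {}
    relations: list[RelationInstance] = []
    relation_tags: list[str] = []
    seen_relations: set[tuple[str, str, str]] = set()

    for segment in segments:
        mentions, tags = extract_entities(segment, kb, backend, config)
        entities_by_segment[segment.seg_index] = mentions
        all_entities.extend(mentions)
        entity_tags.extend(tags)
        for rel in extract_relations(segment, mentions, kb, backend, config):
            key = _relation_key(rel)
            if key not in seen_relations:
                seen_relations.add(key)
                relations.append(rel)
                relation_tags.append(f"segment:{segment.seg_index}")

    if config.bridge_enabled and len(segments) > 1:
        for window in bridge_windows(
            doc_text, segments, config.bridge_tokens, tokenizer_spec="whitespace"
        ):
            flanking = entities_by_segment.get(window.seg_index, []) + entities_by_segment.get(
                window.seg_index + 1, []
            )
            in_window = [
                m
                for m in flanking
                if m.span is None
                or (window.char_start <= m.span[0] and m.span[1] <= window.char_end)
            ]
            for rel in extract_relations(window, in_window, kb, backend, config):
                key = _relation_key(rel)
                if key not in seen_relations:
                    seen_relations.add(key)
                    relations.append(rel)
                    relation_tags.append(f"bridge:{window.seg_index}")

    tag_by_mention = {m.mention_id: t for m, t in zip(all_entities, entity_tags)}
    all_entities, relations_kept = calibrate(
        all_entities, relations, backend, config.calibration_mode, config, doc_id
    )
    kept_keys = {_relation_key(r) for r in relations_kept}
    relation_tags = [t for r, t in zip(relations, relation_tags) if _relation_key(r) in kept_keys]
    entity_tags = [tag_by_mention.get(m.mention_id, "") for m in all_entities]
    return ExtractionResult(
        doc_id=doc_id,
        entities=all_entities,
        relations=relations_kept,
        provenance={"entities": entity_tags, "relations": relation_tags},
    )
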