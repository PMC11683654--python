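"""Prompt rendering for the four pipeline stages.

Each stage has a plain-text template shipped with the package (and
overridable via a prompts directory) holding the static wording of four
sections — task description, type definitions, the "notice" guideline block,
and the output format.  Rendering assembles, in fixed order::

    stage marker -> task_description -> definitions -> notice -> exemplars
                 -> slots -> output_format

The notice block is the hand-tunable guideline text correcting known model
misinterpretations; it, the exemplars, and the injected ontology knowledge
are the three ablation axes.  Toggles only add or remove whole sections.

Slots carry machine-readable payloads (fenced JSON tagged ``[slot:<name>]``)
so the deterministic mock backend can recover them; an empty slot renders an
explicit "none found" marker.  Rendering is pure and deterministic.  When a
rendered prompt exceeds the token budget (default ~1000 instruction tokens
plus the passage), exemplars are dropped from the end, then knowledge slots
are truncated — the passage text is never cut.
"""

from __future__ import annotations

import json
import logging
import random
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .corpus_io import AnnotatedDocument, EntityMention, RelationInstance
from .llm_runtime import STAGE_MARKER_TEMPLATE
from .normalize import normalize_name
from .ontology_kb import AssociationTriple, OntologyConcept
from .preprocess import Segment, count_tokens
from .term_matcher import TermMatch

logger = logging.getLogger(__name__)

DEFAULT_PROMPT_BUDGET_TOKENS = 1000

SECTION_KINDS = ("task_description", "definitions", "notice", "exemplars", "output_format")
_SECTION_HEADER = re.compile(r"^\[section:(\w+)\]\s*$", re.MULTILINE)


@dataclass(frozen=True)
class Exemplar:
    """A gold input-output pair inserted into a prompt for in-context learning."""

    input_text: str
    gold_output_json: str
    source_doc_id: str


@dataclass(frozen=True)
class AblationToggles:
    use_knowledge: bool = True
    use_exemplars: bool = True
    use_notice: bool = True


@dataclass(frozen=True)
class PromptTemplate:
    stage: str
    sections: tuple[tuple[str, str], ...]

    def section(self, kind: str) -> str:
        for k, text in self.sections:
            if k == kind:
                return text
        return ""


def load_template(stage: str, prompts_dir: str | Path | None = None) -> PromptTemplate:
    """Load a stage template, from ``prompts_dir`` when given, else from the
    copies shipped inside the package."""
    return _load_template_cached(stage, str(prompts_dir) if prompts_dir is not None else None)


@lru_cache(maxsize=32)
def _load_template_cached(stage: str, prompts_dir: str | None) -> PromptTemplate:
    if prompts_dir is not None:
        raw = (Path(prompts_dir) / f"{stage}.txt").read_text(encoding="utf-8")
    else:
        raw = resources.files("raremine").joinpath(f"templates/{stage}.txt").read_text("utf-8")
    pieces = _SECTION_HEADER.split(raw)
    sections = []
    # pieces alternate: [preamble, kind, text, kind, text, ...]
    for kind, text in zip(pieces[1::2], pieces[2::2]):
        if kind not in SECTION_KINDS:
            raise ValueError(f"template {stage}: unknown section {kind!r}")
        sections.append((kind, text.strip()))
    return PromptTemplate(stage=stage, sections=tuple(sections))


# ---------------------------------------------------------------------------
# exemplar selection

def _stage_gold_json(doc: AnnotatedDocument, stage: str) -> str:
    if stage in ("extract_more_terms",):
        terms = [m.surface for m in doc.entities if m.entity_type != "anaphor"]
        anaphors = [m.surface for m in doc.entities if m.entity_type == "anaphor"]
        return json.dumps({"terms": terms, "anaphors": anaphors})
    if stage == "extract_entities":
        return json.dumps(
            {"entities": [{"text": m.surface, "type": m.entity_type} for m in doc.entities]}
        )
    if stage == "extract_relations":
        relations = []
        for rel in doc.relations:
            subj = doc.mention_by_id(rel.subject_ref)
            obj = doc.mention_by_id(rel.object_ref)
            relations.append(
                {
                    "subject": subj.surface if subj else rel.subject_ref,
                    "type": rel.relation_type,
                    "object": obj.surface if obj else rel.object_ref,
                }
            )
        return json.dumps({"relations": relations})
    raise ValueError(f"no gold serialization for stage {stage!r}")


def select_exemplars(
    train_docs: list[AnnotatedDocument],
    k: int = 5,
    seed: int = 0,
    stage: str = "extract_entities",
) -> list[Exemplar]:
    """Seeded uniform sample of ``k`` training documents, serialized as gold
    input-output pairs in the stage's output schema."""
    if k > len(train_docs):
        raise ValueError(f"cannot sample {k} exemplars from {len(train_docs)} documents")
    sample = random.Random(seed).sample(train_docs, k)
    return [
        Exemplar(
            input_text=doc.text,
            gold_output_json=_stage_gold_json(doc, stage),
            source_doc_id=doc.doc_id,
        )
        for doc in sample
    ]


# ---------------------------------------------------------------------------
# assembly

def _marker(stage: str, segment: Segment | None, doc_id: str = "") -> str:
    if segment is not None:
        return STAGE_MARKER_TEMPLATE.format(
            stage=stage,
            doc_id=segment.doc_id,
            start=segment.char_start,
            end=segment.char_end,
            bridge=int(segment.is_bridge),
        )
    return STAGE_MARKER_TEMPLATE.format(stage=stage, doc_id=doc_id, start=0, end=0, bridge=0)


def _json_slot(name: str, payload) -> str:
    if not payload:
        return f"[slot:{name}]\n(none found)"
    return f"[slot:{name}]\n```json\n{json.dumps(payload, indent=0)}\n```"


def _text_slot(text: str) -> str:
    return f"[slot:text]\nPassage:\n{text}\n[end of passage]"


def _exemplar_block(exemplars: list[Exemplar]) -> str:
    parts = ["Examples of correct input and output:"]
    for i, ex in enumerate(exemplars, start=1):
        parts.append(f"--- Example {i} (input) ---\n{ex.input_text}")
        parts.append(f"--- Example {i} (output) ---\n{ex.gold_output_json}")
    return "\n".join(parts)


def _assemble(
    stage: str,
    template: PromptTemplate,
    marker: str,
    toggles: AblationToggles,
    slot_parts: list[str],
    exemplars: list[Exemplar],
    truncatable_slots: dict[str, list],
    segment_text_tokens: int,
    budget_tokens: int,
    tokenizer_spec: str,
    rebuild_slots,
) -> str:
    """Join the sections in canonical order, then enforce the token budget by
    dropping exemplars from the end and truncating knowledge slots."""
    exemplars = list(exemplars) if toggles.use_exemplars else []

    def build(current_exemplars, current_slots) -> str:
        parts = [marker, template.section("task_description"), template.section("definitions")]
        if toggles.use_notice and template.section("notice"):
            parts.append(template.section("notice"))
        if current_exemplars:
            parts.append(_exemplar_block(current_exemplars))
        parts.extend(current_slots)
        parts.append(template.section("output_format"))
        return "\n\n".join(p for p in parts if p)

    budget = budget_tokens + segment_text_tokens
    prompt = build(exemplars, slot_parts)
    while count_tokens(prompt, tokenizer_spec) > budget and exemplars:
        dropped = exemplars.pop()
        logger.warning("prompt over budget: dropping exemplar %s", dropped.source_doc_id)
        prompt = build(exemplars, slot_parts)
    while count_tokens(prompt, tokenizer_spec) > budget and any(
        truncatable_slots.get(n) for n in truncatable_slots
    ):
        for name in truncatable_slots:
            if truncatable_slots[name]:
                truncatable_slots[name].pop()
                logger.warning("prompt over budget: truncating knowledge slot %r", name)
                break
        slot_parts = rebuild_slots(truncatable_slots)
        prompt = build(exemplars, slot_parts)
    return prompt


def _common_kwargs(kwargs) -> tuple[int, str, str | Path | None]:
    return (
        kwargs.pop("budget_tokens", DEFAULT_PROMPT_BUDGET_TOKENS),
        kwargs.pop("tokenizer_spec", "auto"),
        kwargs.pop("prompts_dir", None),
    )


# ---------------------------------------------------------------------------
# stage renderers

def render_extract_more_terms(
    segment: Segment,
    matches: list[TermMatch],
    toggles: AblationToggles = AblationToggles(),
    **kwargs,
) -> str:
    """Stage-2 prompt: the passage plus the dictionary hits (with negation
    flags and lexicon definitions), asking for additional terms and anaphors."""
    budget, tokenizer_spec, prompts_dir = _common_kwargs(kwargs)
    template = kwargs.pop("template", None) or load_template("extract_more_terms", prompts_dir)
    payload = [
        {"text": m.surface, "negated": m.negated, "definition": m.definition} for m in matches
    ]
    slots = [_text_slot(segment.text), _json_slot("matched_terms", payload)]
    return _assemble(
        "extract_more_terms", template, _marker("extract_more_terms", segment), toggles,
        slots, [], {}, count_tokens(segment.text, tokenizer_spec), budget, tokenizer_spec,
        lambda _t: slots,
    )


def render_entity_prompt(
    segment: Segment,
    terms: list,
    anaphors: list[str],
    exemplars: list[Exemplar],
    rd_knowledge: list[OntologyConcept],
    toggles: AblationToggles = AblationToggles(),
    **kwargs,
) -> str:
    """Stage-3 prompt: candidate terms, anaphors, exemplars and rare-disease
    knowledge (name + definition for candidates that hit the rare-disease
    lexicon), asking for typed entities."""
    budget, tokenizer_spec, prompts_dir = _common_kwargs(kwargs)
    template = kwargs.pop("template", None) or load_template("extract_entities", prompts_dir)
    term_payload = [
        t if isinstance(t, dict) else {"text": str(t)} for t in terms
    ]
    knowledge = [
        {"name": c.preferred_name, "definition": c.definition} for c in rd_knowledge
    ]
    truncatable = {"rare_disease_knowledge": knowledge} if toggles.use_knowledge else {}

    def build_slots(trunc) -> list[str]:
        slots = [
            _text_slot(segment.text),
            _json_slot("candidate_terms", term_payload),
            _json_slot("anaphors", list(anaphors)),
        ]
        if toggles.use_knowledge:
            slots.append(_json_slot("rare_disease_knowledge", trunc["rare_disease_knowledge"]))
        return slots

    return _assemble(
        "extract_entities", template, _marker("extract_entities", segment), toggles,
        build_slots(truncatable) if toggles.use_knowledge else build_slots({}), exemplars,
        truncatable, count_tokens(segment.text, tokenizer_spec), budget, tokenizer_spec,
        build_slots,
    )


def render_relation_prompt(
    segment: Segment,
    entities: list[EntityMention],
    associations: list[AssociationTriple],
    exemplars: list[Exemplar],
    toggles: AblationToggles = AblationToggles(),
    **kwargs,
) -> str:
    """Relation-stage prompt: the typed entity list plus, under the knowledge
    toggle, the ontology's (rare disease, frequency, phenotype) triples for
    rare-disease entities present in the passage."""
    budget, tokenizer_spec, prompts_dir = _common_kwargs(kwargs)
    template = kwargs.pop("template", None) or load_template("extract_relations", prompts_dir)
    entity_payload = [{"text": m.surface, "type": m.entity_type} for m in entities]
    triples = [
        {
            "rare_disease": t.rare_disease_name,
            "frequency": t.frequency_label,
            "phenotype": t.phenotype_name,
        }
        for t in associations
    ]
    truncatable = {"associations": triples} if toggles.use_knowledge else {}

    def build_slots(trunc) -> list[str]:
        slots = [_text_slot(segment.text), _json_slot("entities", entity_payload)]
        if toggles.use_knowledge:
            slots.append(_json_slot("associations", trunc["associations"]))
        return slots

    return _assemble(
        "extract_relations", template, _marker("extract_relations", segment), toggles,
        build_slots(truncatable) if toggles.use_knowledge else build_slots({}), exemplars,
        truncatable, count_tokens(segment.text, tokenizer_spec), budget, tokenizer_spec,
        build_slots,
    )


def render_calibration_prompt(
    entities: list[EntityMention],
    relations: list[RelationInstance],
    doc_id: str = "",
    toggles: AblationToggles = AblationToggles(),
    **kwargs,
) -> str:
    """Calibration prompt: every entity with the number of relations it
    participates in, asking for the retained-entity list."""
    budget, tokenizer_spec, prompts_dir = _common_kwargs(kwargs)
    template = kwargs.pop("template", None) or load_template("calibrate", prompts_dir)
    counts: dict[str, int] = {}
    for rel in relations:
        for ref in (rel.subject_ref, rel.object_ref):
            counts[normalize_name(ref)] = counts.get(normalize_name(ref), 0) + 1
    payload = [
        {
            "text": m.surface,
            "type": m.entity_type,
            "relation_count": counts.get(normalize_name(m.surface), 0),
        }
        for m in entities
    ]
    slots = [_json_slot("candidate_entities", payload)]
    return _assemble(
        "calibrate", template, _marker("calibrate", None, doc_id), toggles,
        slots, [], {}, 0, budget, tokenizer_spec, lambda _t: slots,
    )
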