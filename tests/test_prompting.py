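"""Prompt template assembly, toggles, exemplar sampling, budget enforcement."""

import json

import pytest

from raremine.corpus_io import AnnotatedDocument, EntityMention, RelationInstance
from raremine.llm_runtime import parse_slot_blocks, parse_stage_marker
from raremine.ontology_kb import AssociationTriple, OntologyConcept
from raremine.preprocess import Segment
from raremine.prompting import (
    AblationToggles,
    Exemplar,
    load_template,
    render_calibration_prompt,
    render_entity_prompt,
    render_extract_more_terms,
    render_relation_prompt,
    select_exemplars,
)
from raremine.term_matcher import TermMatch


def seg(text="Patients with Fryns syndrome develop fatigue.", doc="d1"):
    return Segment(doc, 0, text, 0, len(text), len(text.split()))


@pytest.fixture
def exemplars():
    doc = AnnotatedDocument(
        "train1", "FS causes rash.",
        [EntityMention("FS", "rare_disease", (0, 2), "T1"),
         EntityMention("rash", "symptom_and_sign", (10, 14), "T2")],
        [RelationInstance("produces", "T1", "T2")],
    )
    return select_exemplars([doc], k=1, stage="extract_entities")


class TestSelectExemplars:
    def _train(self, n):
        return [AnnotatedDocument(f"t{i}", f"text {i}") for i in range(n)]

    def test_deterministic_for_fixed_seed(self):
        docs = self._train(50)
        a = select_exemplars(docs, 5, seed=42)
        b = select_exemplars(docs, 5, seed=42)
        assert [e.source_doc_id for e in a] == [e.source_doc_id for e in b]

    def test_k_zero_and_k_equals_n(self):
        docs = self._train(4)
        assert select_exemplars(docs, 0) == []
        ids = {e.source_doc_id for e in select_exemplars(docs, 4, seed=1)}
        assert ids == {d.doc_id for d in docs}

    def test_k_over_n_rejected(self):
        with pytest.raises(ValueError):
            select_exemplars(self._train(3), 5)

    def test_gold_output_conforms_to_stage_schema(self):
        doc = AnnotatedDocument(
            "t", "ab cd",
            [EntityMention("ab", "rare_disease", (0, 2), "T1"),
             EntityMention("cd", "anaphor", (3, 5), "T2")],
            [RelationInstance("anaphora", "T2", "T1")],
        )
        [ent] = select_exemplars([doc], 1, stage="extract_entities")
        assert json.loads(ent.gold_output_json)["entities"][0]["type"] == "rare_disease"
        [rel] = select_exemplars([doc], 1, stage="extract_relations")
        assert json.loads(rel.gold_output_json)["relations"] == [
            {"subject": "cd", "type": "anaphora", "object": "ab"}
        ]


class TestRenderExtractMoreTerms:
    def test_all_sections_present_in_order(self):
        matches = [TermMatch("fatigue", "HP:1", (38, 45), negated=False, definition="tiredness")]
        prompt = render_extract_more_terms(seg(), matches)
        marker = parse_stage_marker(prompt)
        assert marker["stage"] == "extract_more_terms" and marker["doc_id"] == "d1"
        order = [prompt.index(s) for s in ("anaphors", "Notice:", "[slot:text]", "[slot:matched_terms]", "JSON object")]
        assert order == sorted(order)
        slots = parse_slot_blocks(prompt)
        assert slots["matched_terms"][0]["definition"] == "tiredness"

    def test_notice_toggle_removes_only_that_section(self):
        with_notice = render_extract_more_terms(seg(), [])
        without = render_extract_more_terms(seg(), [], AblationToggles(use_notice=False))
        assert "Notice:" in with_notice and "Notice:" not in without
        assert len(without) < len(with_notice)

    def test_empty_match_list_renders_none_marker(self):
        prompt = render_extract_more_terms(seg(), [])
        assert "[slot:matched_terms]\n(none found)" in prompt


class TestRenderEntityPrompt:
    def test_knowledge_slot_carries_name_and_definition(self, exemplars):
        rd = OntologyConcept("ORPHA:1", "Fryns syndrome", definition="A rare syndrome.", category="rare_disease")
        prompt = render_entity_prompt(seg(), [{"text": "Fryns syndrome"}], [], exemplars, [rd])
        slots = parse_slot_blocks(prompt)
        assert slots["rare_disease_knowledge"] == [
            {"name": "Fryns syndrome", "definition": "A rare syndrome."}
        ]

    def test_knowledge_toggle_removes_the_slot(self, exemplars):
        rd = OntologyConcept("ORPHA:1", "Fryns syndrome", category="rare_disease")
        prompt = render_entity_prompt(
            seg(), [], [], exemplars, [rd], AblationToggles(use_knowledge=False)
        )
        assert "rare_disease_knowledge" not in prompt

    def test_exemplars_render_in_sample_order(self):
        docs = [AnnotatedDocument(f"t{i}", f"text number {i}") for i in range(6)]
        chosen = select_exemplars(docs, 5, seed=2)
        prompt = render_entity_prompt(seg(), [], [], chosen, [])
        positions = [prompt.index(e.input_text) for e in chosen]
        assert positions == sorted(positions)

    def test_exemplar_toggle(self, exemplars):
        prompt = render_entity_prompt(
            seg(), [], [], exemplars, [], AblationToggles(use_exemplars=False)
        )
        assert "Example 1" not in prompt

    def test_output_format_enumerates_the_four_types(self):
        prompt = render_entity_prompt(seg(), [], [], [], [])
        tail = prompt[prompt.rindex("JSON object"):]
        for etype in ("rare_disease", "disease", "symptom_and_sign", "anaphor"):
            assert etype in tail


class TestRenderRelationPrompt:
    def test_association_triples_rendered_for_rare_disease_entities(self):
        entities = [EntityMention("Fryns syndrome", "rare_disease", None, "e0")]
        triples = [
            AssociationTriple("Fryns syndrome", "very frequent", "fatigue"),
            AssociationTriple("Fryns syndrome", "occasional", "rash"),
        ]
        prompt = render_relation_prompt(seg(), entities, triples, [])
        slots = parse_slot_blocks(prompt)
        assert len(slots["associations"]) == 2
        assert slots["entities"] == [{"text": "Fryns syndrome", "type": "rare_disease"}]

    def test_no_rare_disease_entities_renders_none(self):
        prompt = render_relation_prompt(seg(), [], [], [])
        assert "[slot:associations]\n(none found)" in prompt

    def test_all_six_relation_types_named(self):
        prompt = render_relation_prompt(seg(), [], [], [])
        for rtype in ("produces", "increases_risk_of", "is_a", "is_acron", "is_synon", "anaphora"):
            assert rtype in prompt


class TestRenderCalibrationPrompt:
    def test_relation_counts_attached(self):
        entities = [
            EntityMention("Fryns syndrome", "rare_disease", None, "e0"),
            EntityMention("fatigue", "symptom_and_sign", None, "e1"),
            EntityMention("disorder", "disease", None, "e2"),
        ]
        relations = [RelationInstance("produces", "Fryns syndrome", "fatigue")]
        prompt = render_calibration_prompt(entities, relations, "d1")
        slots = parse_slot_blocks(prompt)
        counts = {e["text"]: e["relation_count"] for e in slots["candidate_entities"]}
        assert counts == {"Fryns syndrome": 1, "fatigue": 1, "disorder": 0}

    def test_empty_input_minimal_prompt(self):
        prompt = render_calibration_prompt([], [], "d1")
        assert "(none found)" in prompt
        assert parse_stage_marker(prompt)["stage"] == "calibrate"

    def test_rendering_is_deterministic(self):
        entities = [EntityMention("fatigue", "symptom_and_sign", None, "e0")]
        assert render_calibration_prompt(entities, [], "d") == render_calibration_prompt(entities, [], "d")


class TestBudget:
    def test_over_budget_drops_exemplars_from_the_end(self):
        docs = [AnnotatedDocument(f"t{i}", "filler " * 300) for i in range(4)]
        chosen = select_exemplars(docs, 4, seed=0)
        prompt = render_entity_prompt(
            seg(), [], [], chosen, [], budget_tokens=400, tokenizer_spec="whitespace"
        )
        kept = prompt.count("--- Example")
        assert kept < 2 * len(chosen)
        # the passage itself is never cut
        assert seg().text in prompt

    def test_templates_load_with_expected_sections(self):
        for stage in ("extract_more_terms", "extract_entities", "extract_relations", "calibrate"):
            template = load_template(stage)
            kinds = [k for k, _ in template.sections]
            assert kinds[0] == "task_description" and kinds[-1] == "output_format"
            assert "notice" in kinds


class TestExemplarInvariant:
    def test_gold_json_parses_for_every_exemplar(self, exemplars):
        for e in exemplars:
            assert isinstance(json.loads(e.gold_output_json), dict)

    def test_exemplar_is_frozen(self, exemplars):
        with pytest.raises(AttributeError):
            exemplars[0].input_text = "changed"
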