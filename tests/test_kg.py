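"""Graph construction: normalization, anaphora rewriting, merging, export."""

import pytest

from raremine.corpus_io import EntityMention, RelationInstance
from raremine.kg import (
    build_graph,
    export_graph,
    import_csv_pair,
    normalize_name,
    resolve_anaphora,
)
from raremine.pipeline import ExtractionResult


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Fryns Syndrome", "fryns syndrome"),
            ("fryns syndrome", "fryns syndrome"),
            ("  giant  cell myocarditis ", "giant cell myocarditis"),
        ],
    )
    def test_casefold_trim_collapse(self, raw, expected):
        assert normalize_name(raw) == expected

    def test_idempotent(self):
        for s in ("A  B", " x ", "Já  Tu"):
            assert normalize_name(normalize_name(s)) == normalize_name(s)


def _result(entities, relations, doc="d1"):
    return ExtractionResult(doc, entities, relations)


def _simple_anaphoric_result():
    entities = [
        EntityMention("Fryns syndrome", "rare_disease", (0, 14), "e0"),
        EntityMention("this disease", "anaphor", (20, 32), "e1"),
        EntityMention("fatigue", "symptom_and_sign", (42, 49), "e2"),
    ]
    relations = [
        RelationInstance("anaphora", "this disease", "Fryns syndrome"),
        RelationInstance("produces", "this disease", "fatigue"),
    ]
    return _result(entities, relations)


class TestResolveAnaphora:
    def test_relation_rewritten_to_antecedent(self):
        resolved = resolve_anaphora(_simple_anaphoric_result())
        assert resolved.relations == [
            RelationInstance("produces", "Fryns syndrome", "fatigue")
        ]
        assert all(m.entity_type != "anaphor" for m in resolved.entities)

    def test_no_anaphors_is_identity(self):
        result = _result(
            [EntityMention("fatigue", "symptom_and_sign", None, "e0")],
            [],
        )
        assert resolve_anaphora(result) is result

    def test_multi_antecedent_uses_nearest_preceding(self, caplog):
        entities = [
            EntityMention("Alpha syndrome", "rare_disease", (0, 14), "e0"),
            EntityMention("Beta syndrome", "rare_disease", (20, 33), "e1"),
            EntityMention("this disease", "anaphor", (40, 52), "e2"),
            EntityMention("rash", "symptom_and_sign", (60, 64), "e3"),
        ]
        relations = [
            RelationInstance("anaphora", "this disease", "Alpha syndrome"),
            RelationInstance("anaphora", "this disease", "Beta syndrome"),
            RelationInstance("produces", "this disease", "rash"),
        ]
        resolved = resolve_anaphora(_result(entities, relations))
        assert RelationInstance("produces", "Beta syndrome", "rash") in resolved.relations

    def test_unlinked_anaphor_removed_with_its_relations(self):
        entities = [
            EntityMention("this disease", "anaphor", (0, 12), "e0"),
            EntityMention("rash", "symptom_and_sign", (20, 24), "e1"),
        ]
        relations = [RelationInstance("produces", "this disease", "rash")]
        resolved = resolve_anaphora(_result(entities, relations))
        assert resolved.relations == []
        assert all(m.entity_type != "anaphor" for m in resolved.entities)


class TestBuildGraph:
    def test_same_triple_from_two_documents_merges_with_support(self):
        def one(doc):
            return _result(
                [EntityMention("Fryns Syndrome", "rare_disease", None, "e0"),
                 EntityMention("fatigue", "symptom_and_sign", None, "e1")],
                [RelationInstance("produces", "Fryns Syndrome", "fatigue")],
                doc,
            )

        kg = build_graph([one("d1"), one("d2")])
        assert kg.edge_count == 1
        assert kg.edges[("fryns syndrome", "produces", "fatigue")].support_count == 2
        assert kg.nodes["fryns syndrome"].display_name == "Fryns Syndrome"

    def test_empty_input_empty_graph(self):
        kg = build_graph([])
        assert kg.node_count == 0 and kg.edge_count == 0

    def test_star_of_one_disease_and_three_phenotypes(self):
        entities = [EntityMention("Turcot syndrome", "rare_disease", None, "e0")]
        relations = []
        for i, symptom in enumerate(("abdominal pain", "bleeding", "fatigue")):
            entities.append(EntityMention(symptom, "symptom_and_sign", None, f"s{i}"))
            relations.append(RelationInstance("produces", "Turcot syndrome", symptom))
        kg = build_graph([_result(entities, relations)])
        assert kg.node_count == 4 and kg.edge_count == 3
        assert all(e.subject_key == "turcot syndrome" for e in kg.edges.values())

    def test_isolated_nodes_excluded(self):
        result = _result(
            [EntityMention("loner", "disease", None, "e0"),
             EntityMention("a", "disease", None, "e1"),
             EntityMention("b", "symptom_and_sign", None, "e2")],
            [RelationInstance("produces", "a", "b")],
        )
        kg = build_graph([result])
        assert set(kg.nodes) == {"a", "b"}

    def test_type_conflict_resolved_by_specificity(self):
        results = [
            _result(
                [EntityMention("x", "disease", None, "e0"),
                 EntityMention("y", "symptom_and_sign", None, "e1")],
                [RelationInstance("produces", "x", "y")],
                "d1",
            ),
            _result(
                [EntityMention("x", "rare_disease", None, "e0"),
                 EntityMention("y", "symptom_and_sign", None, "e1")],
                [RelationInstance("produces", "x", "y")],
                "d2",
            ),
        ]
        kg = build_graph(results)
        assert kg.nodes["x"].node_type == "rare_disease"

    def test_final_graph_has_no_anaphor_nodes_or_anaphora_edges(self):
        kg = build_graph([_simple_anaphoric_result()])
        assert all(n.node_type != "anaphor" for n in kg.nodes.values())
        assert all(key[1] != "anaphora" for key in kg.edges)


class TestExport:
    @pytest.fixture
    def kg(self):
        return build_graph([_simple_anaphoric_result()])

    def test_csv_pair_row_counts_and_round_trip(self, kg, tmp_path):
        nodes_path, edges_path = export_graph(kg, "csv_pair", tmp_path)
        assert len(nodes_path.read_text().splitlines()) == 1 + kg.node_count
        assert len(edges_path.read_text().splitlines()) == 1 + kg.edge_count
        again = import_csv_pair(nodes_path, edges_path)
        assert set(again.nodes) == set(kg.nodes)
        assert again.edges == kg.edges

    def test_empty_graph_headers_only(self, tmp_path):
        nodes_path, edges_path = export_graph(build_graph([]), "csv_pair", tmp_path)
        assert nodes_path.read_text().strip() == "key,name,type"
        assert edges_path.read_text().strip() == "subject,relation,object,support"

    def test_graphml_and_cypher_written(self, kg, tmp_path):
        [graphml] = export_graph(kg, "graphml", tmp_path)
        assert graphml.stat().st_size > 0
        [cypher] = export_graph(kg, "cypher", tmp_path)
        content = cypher.read_text()
        assert content.count("MERGE") == kg.node_count + kg.edge_count

    def test_unknown_format_rejected(self, kg, tmp_path):
        with pytest.raises(ValueError):
            export_graph(kg, "rdf", tmp_path)
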