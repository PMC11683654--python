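"""Scoring semantics, reporting arithmetic, confusion matrices."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from raremine.corpus_io import (
    ENTITY_TYPES,
    AnnotatedDocument,
    EntityMention,
    RelationInstance,
)
from raremine.evaluation import (
    confusion_matrices,
    evaluate_corpus,
    metrics_from_dict,
    metrics_to_dict,
    overall_score,
    report,
    round_half_up,
    score_entities,
    score_relations,
)
from raremine.pipeline import ExtractionResult


def ment(name, etype="symptom_and_sign"):
    return EntityMention(name, etype, None, "")


def rel(s, t, o):
    return RelationInstance(t, s, o)


def brute_force_matched(pred, gold):
    """Optimal bipartite matching size where pred i may pair with gold j iff
    their (normalized name, type) keys are equal — the independent oracle for
    the greedy multiset scorer."""
    g = nx.Graph()
    for i, p in enumerate(pred):
        g.add_node(("p", i))
    for j, q in enumerate(gold):
        g.add_node(("g", j))
    for i, p in enumerate(pred):
        for j, q in enumerate(gold):
            if p.surface.lower() == q.surface.lower() and p.entity_type == q.entity_type:
                g.add_edge(("p", i), ("g", j))
    return len(nx.algorithms.matching.max_weight_matching(g, maxcardinality=True))


class TestScoreEntities:
    def test_identical_lists_score_100(self):
        mentions = [ment("anemia"), ment("rash"), ment("Fryns", "rare_disease")]
        per_type, overall = score_entities(mentions, mentions)
        assert overall.precision == overall.recall == overall.f1 == 100.0
        assert per_type["rare_disease"].f1 == 100.0

    def test_replicated_gold_counts_per_occurrence(self):
        gold = [ment("anemia"), ment("anemia")]
        pred = [ment("anemia")]
        per_type, overall = score_entities(pred, gold)
        assert per_type["symptom_and_sign"].recall == 50.0
        assert per_type["symptom_and_sign"].precision == 100.0

    def test_wrong_type_is_miss_plus_false_positive(self):
        gold = [ment("fabry", "rare_disease")]
        pred = [ment("fabry", "disease")]
        per_type, overall = score_entities(pred, gold)
        assert per_type["rare_disease"].recall == 0.0
        assert per_type["disease"].precision == 0.0
        assert overall.f1 == 0.0

    def test_name_match_is_case_insensitive(self):
        per_type, overall = score_entities([ment("RASH")], [ment("rash")])
        assert overall.f1 == 100.0

    def test_empty_pred_reports_zero_with_flag(self):
        metrics = evaluate_corpus(
            [ExtractionResult("d")], [AnnotatedDocument("d", "x", [ment("rash")])]
        )
        assert metrics.entity_overall.precision == 0.0
        assert metrics.entity_overall.recall == 0.0
        assert any("undefined" in f for f in metrics.flags)

    def test_document_scoping_prevents_cross_document_matches(self):
        pred = {"d1": [ment("rash")], "d2": []}
        gold = {"d1": [], "d2": [ment("rash")]}
        _, overall = score_entities(pred, gold)
        assert overall.matched == 0

    @settings(deadline=None, max_examples=60)
    @given(
        pred_names=st.lists(st.sampled_from("abcd"), max_size=10),
        gold_names=st.lists(st.sampled_from("abcd"), max_size=10),
        seed=st.integers(0, 5),
    )
    def test_greedy_equals_optimal_bipartite_matching(self, pred_names, gold_names, seed):
        rng = random.Random(seed)
        pred = [ment(n, rng.choice(ENTITY_TYPES)) for n in pred_names]
        gold = [ment(n, rng.choice(ENTITY_TYPES)) for n in gold_names]
        _, overall = score_entities(pred, gold)
        assert overall.matched == brute_force_matched(pred, gold)

    def test_symmetric_under_document_order_permutation(self):
        docs = {f"d{i}": [ment(n) for n in ("a", "b")[: i % 3]] for i in range(5)}
        golds = {f"d{i}": [ment("a")] for i in range(5)}
        _, fwd = score_entities(docs, golds)
        rev_docs = dict(reversed(list(docs.items())))
        rev_golds = dict(reversed(list(golds.items())))
        _, bwd = score_entities(rev_docs, rev_golds)
        assert (fwd.matched, fwd.n_pred, fwd.n_gold) == (bwd.matched, bwd.n_pred, bwd.n_gold)


class TestScoreRelations:
    def test_identical_scores_100(self):
        rels = [rel("a", "produces", "b"), rel("c", "is_a", "d")]
        per_type, overall = score_relations(rels, rels)
        assert overall.f1 == 100.0

    def test_case_only_subject_difference_still_matches(self):
        _, overall = score_relations(
            [rel("Fryns Syndrome", "produces", "rash")],
            [rel("fryns syndrome", "produces", "rash")],
        )
        assert overall.f1 == 100.0

    def test_partial_credit_counts(self):
        gold = [rel("a", "produces", "b"), rel("a", "produces", "c")]
        pred = [rel("a", "produces", "b"), rel("x", "is_a", "y")]
        per_type, _ = score_relations(pred, gold)
        assert per_type["produces"].recall == 50.0
        assert per_type["is_a"].precision == 0.0

    def test_matching_independent_of_entity_correctness(self):
        # relation names matching is all that matters
        _, overall = score_relations([rel("a", "is_a", "b")], [rel("a", "is_a", "b")])
        assert overall.matched == 1


class TestOverallScore:
    @pytest.mark.parametrize(
        "entity_f1,relation_f1,expected",
        [
            (44.7, 21.1, 32.9),
            (53.8, 36.1, 45.0),  # half-up at the midpoint
            (52.9, 34.9, 43.9),
            (44.7, 33.7, 39.2),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_mean_reported_to_one_decimal(self, entity_f1, relation_f1, expected):
        assert overall_score(entity_f1, relation_f1) == expected

    def test_round_half_up_examples(self):
        assert round_half_up(44.95) == 45.0
        assert round_half_up(44.94) == 44.9
        assert round_half_up(-0.05) == -0.1  # toward larger magnitude at .5


class TestConfusionMatrices:
    def _pair(self, gold_entities, pred_entities):
        gold = [AnnotatedDocument("d", "x", gold_entities)]
        pred = [ExtractionResult("d", pred_entities)]
        return confusion_matrices(pred, gold)

    def test_perfect_predictions_are_diagonal(self):
        mentions = [ment("a", "rare_disease"), ment("b", "disease")]
        ent_cm, _ = self._pair(mentions, mentions)
        assert ent_cm.cell("rare_disease", "rare_disease") == 1
        assert ent_cm.cell("disease", "disease") == 1
        assert ent_cm.row_sum("Error") == 0

    def test_type_confusion_lands_in_the_off_diagonal_cell(self):
        ent_cm, _ = self._pair([ment("x", "rare_disease")], [ment("x", "disease")])
        assert ent_cm.cell("rare_disease", "disease") == 1

    def test_unmatched_gold_and_pred_go_to_error(self):
        ent_cm, _ = self._pair([ment("missed", "anaphor")], [ment("spurious", "disease")])
        assert ent_cm.cell("anaphor", "Error") == 1
        assert ent_cm.cell("Error", "disease") == 1

    def test_replicated_mentions_counted_once(self):
        ent_cm, _ = self._pair(
            [ment("dup", "disease"), ment("dup", "disease")],
            [ment("dup", "disease"), ment("dup", "disease")],
        )
        assert ent_cm.cell("disease", "disease") == 1

    def test_row_sums_equal_deduplicated_gold_counts(self):
        gold = [ment("a", "disease"), ment("a", "disease"), ment("b", "disease")]
        ent_cm, _ = self._pair(gold, [])
        assert ent_cm.row_sum("disease") == 2


class TestReport:
    @pytest.fixture
    def metrics(self):
        gold = [AnnotatedDocument("d", "x", [ment("a"), ment("b", "disease")],
                                  [RelationInstance("produces", "a", "b")])]
        pred = [ExtractionResult("d", [ment("a")], [rel("a", "produces", "b")])]
        return evaluate_corpus(pred, gold)

    def test_json_round_trips(self, metrics):
        again = metrics_from_dict(metrics_to_dict(metrics))
        assert again.entity_overall == metrics.entity_overall
        assert again.per_relation_type == metrics.per_relation_type

    def test_text_table_has_per_type_then_overall_rows(self, metrics):
        text = report(metrics, "text_table")
        lines = text.splitlines()
        assert lines[-1].startswith("overall")
        assert any(line.startswith("rare_disease") for line in lines)

    def test_delta_columns_render_signed(self, metrics):
        better = evaluate_corpus(
            [ExtractionResult("d", [ment("a"), ment("b", "disease")],
                              [rel("a", "produces", "b")])],
            [AnnotatedDocument("d", "x", [ment("a"), ment("b", "disease")],
                               [RelationInstance("produces", "a", "b")])],
        )
        text = report(metrics, "text_table", reference=better)
        assert "-" in text.splitlines()[-1]  # the degraded run shows a negative delta

    def test_empty_corpus_all_zero_with_flags(self):
        metrics = evaluate_corpus([], [])
        assert metrics.overall.f1 == 0.0
        assert metrics.flags

    def test_f1_bounded_by_max_of_p_and_r(self, metrics):
        for prf in [metrics.entity_overall, metrics.relation_overall]:
            assert prf.f1 <= max(prf.precision, prf.recall) + 1e-9
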