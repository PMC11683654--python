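"""Knowledge-graph construction from extraction results.

Entity alignment is lowercase name matching: every mention name is
normalized (case-fold, trim, collapse whitespace) into a node key, and
identical keys merge into one node.  Anaphoric relations are rewritten to
their antecedent's name before graph assembly, so the final graph contains
no anaphor nodes and no anaphora edges.  Duplicate triples merge with a
support count; isolated nodes are excluded, consistent with the calibration
premise that relationless entities are likely irrelevant.

Exports target a Neo4j-loadable form: GraphML, a nodes.csv/edges.csv pair,
or a file of Cypher MERGE statements.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .corpus_io import EntityMention, RelationInstance
from .normalize import normalize_name
from .pipeline import ExtractionResult

logger = logging.getLogger(__name__)

#: when one name carries conflicting types across documents, the more
#: specific diagnosis wins
_TYPE_PRIORITY = {"rare_disease": 0, "disease": 1, "symptom_and_sign": 2}

NODES_CSV_HEADER = ["key", "name", "type"]
EDGES_CSV_HEADER = ["subject", "relation", "object", "support"]


@dataclass(frozen=True)
class KGNode:
    node_key: str
    display_name: str
    node_type: str


@dataclass(frozen=True)
class KGEdge:
    subject_key: str
    object_key: str
    relation_type: str
    support_count: int = 1


@dataclass
class KnowledgeGraph:
    nodes: dict[str, KGNode] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], KGEdge] = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)


def resolve_anaphora(result: ExtractionResult) -> ExtractionResult:
    """Rewrite anaphoric relations to the antecedent's name.

    Each anaphora relation (anaphor subject -> rare-disease antecedent
    object) defines a substitution; every other relation touching that
    anaphor is rewritten to the antecedent.  Anaphora relations and anaphor
    entities are then removed.  An anaphor name linked to several antecedents
    resolves to the nearest preceding one (by mention span when available,
    otherwise the last link in document order) with a warning; anaphors with
    no link are removed along with their relations.
    """
    anaphor_names = {
        normalize_name(m.surface) for m in result.entities if m.entity_type == "anaphor"
    }
    if not anaphor_names and not any(
        r.relation_type == "anaphora" for r in result.relations
    ):
        return result

    antecedent_of: dict[str, str] = {}
    for rel in result.relations:
        if rel.relation_type != "anaphora":
            continue
        key = normalize_name(rel.subject_ref)
        if key in antecedent_of and normalize_name(antecedent_of[key]) != normalize_name(rel.object_ref):
            logger.warning(
                "anaphor %r links to multiple antecedents; keeping the nearest (%r)",
                rel.subject_ref, rel.object_ref,
            )
        # anaphora links arrive in document order, so the last one seen is
        # the nearest preceding antecedent for later mentions
        antecedent_of[key] = rel.object_ref

    entities = [
        m
        for m in result.entities
        if m.entity_type != "anaphor"
    ]
    dropped = anaphor_names - set(antecedent_of)
    if dropped:
        logger.warning("removing %d unlinked anaphor name(s): %s", len(dropped), sorted(dropped))

    relations: list[RelationInstance] = []
    for rel in result.relations:
        if rel.relation_type == "anaphora":
            continue
        subj_key = normalize_name(rel.subject_ref)
        obj_key = normalize_name(rel.object_ref)
        subj = antecedent_of.get(subj_key, rel.subject_ref)
        obj = antecedent_of.get(obj_key, rel.object_ref)
        if (subj_key in dropped) or (obj_key in dropped):
            continue
        relations.append(RelationInstance(rel.relation_type, subj, obj))
    return ExtractionResult(
        doc_id=result.doc_id, entities=entities, relations=relations,
        provenance=result.provenance,
    )


def build_graph(results: Iterable[ExtractionResult]) -> KnowledgeGraph:
    """Merge per-document extraction results into one deduplicated graph.

    Anaphora are resolved first.  Nodes merge by normalized name keeping the
    first-seen display form; a name seen with conflicting types takes the
    highest-priority type (rare_disease over disease over symptom_and_sign),
    logged.  Duplicate (subject, type, object) triples increment the edge's
    support count.  Nodes with no edges are excluded.
    """
    display: dict[str, str] = {}
    types: dict[str, str] = {}
    support: dict[tuple[str, str, str], int] = {}

    def note_entity(m: EntityMention) -> None:
        key = normalize_name(m.surface)
        if not key:
            return
        display.setdefault(key, m.surface)
        old = types.get(key)
        if old is None:
            types[key] = m.entity_type
        elif old != m.entity_type:
            winner = min(
                (old, m.entity_type),
                key=lambda t: _TYPE_PRIORITY.get(t, len(_TYPE_PRIORITY)),
            )
            if winner != old:
                logger.warning(
                    "node %r typed both %r and %r; keeping %r", key, old, m.entity_type, winner
                )
            types[key] = winner

    for result in results:
        resolved = resolve_anaphora(result)
        for m in resolved.entities:
            note_entity(m)
        for rel in resolved.relations:
            skey = normalize_name(rel.subject_ref)
            okey = normalize_name(rel.object_ref)
            if skey not in types or okey not in types:
                logger.warning(
                    "skipping relation %s(%r, %r): endpoint has no entity",
                    rel.relation_type, rel.subject_ref, rel.object_ref,
                )
                continue
            support[(skey, rel.relation_type, okey)] = (
                support.get((skey, rel.relation_type, okey), 0) + 1
            )

    kg = KnowledgeGraph()
    connected = {k for (s, _t, o) in support for k in (s, o)}
    for key in connected:
        kg.nodes[key] = KGNode(key, display[key], types[key])
    for (s, t, o), count in support.items():
        kg.edges[(s, t, o)] = KGEdge(s, o, t, count)
    return kg


# ---------------------------------------------------------------------------
# export / import

def to_networkx(kg: KnowledgeGraph) -> nx.MultiDiGraph:
    graph = nx.MultiDiGraph()
    for node in kg.nodes.values():
        graph.add_node(node.node_key, name=node.display_name, type=node.node_type)
    for edge in kg.edges.values():
        graph.add_edge(
            edge.subject_key, edge.object_key, key=edge.relation_type,
            relation=edge.relation_type, support=edge.support_count,
        )
    return graph


def export_graph(kg: KnowledgeGraph, fmt: str, out_dir: str | Path) -> list[Path]:
    """Write the graph under ``out_dir``; returns the files written.

    ``graphml`` -> graph.graphml; ``csv_pair`` -> nodes.csv + edges.csv
    (bulk-import friendly headers); ``cypher`` -> graph.cypher of MERGE
    statements, one per node and edge.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        path = out_dir / "graph.graphml"
        nx.write_graphml(to_networkx(kg), path)
        return [path]
    if fmt == "csv_pair":
        nodes_path = out_dir / "nodes.csv"
        edges_path = out_dir / "edges.csv"
        with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(NODES_CSV_HEADER)
            for node in sorted(kg.nodes.values(), key=lambda n: n.node_key):
                writer.writerow([node.node_key, node.display_name, node.node_type])
        with open(edges_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(EDGES_CSV_HEADER)
            for (s, t, o), edge in sorted(kg.edges.items()):
                writer.writerow([s, t, o, edge.support_count])
        return [nodes_path, edges_path]
    if fmt == "cypher":
        path = out_dir / "graph.cypher"
        with open(path, "w", encoding="utf-8") as fh:
            for node in sorted(kg.nodes.values(), key=lambda n: n.node_key):
                fh.write(
                    "MERGE (:Entity {key: %s, name: %s, type: %s});\n"
                    % tuple(_cypher_str(v) for v in (node.node_key, node.display_name, node.node_type))
                )
            for (s, t, o), edge in sorted(kg.edges.items()):
                fh.write(
                    "MATCH (a:Entity {key: %s}), (b:Entity {key: %s}) "
                    "MERGE (a)-[:%s {support: %d}]->(b);\n"
                    % (_cypher_str(s), _cypher_str(o), t.upper(), edge.support_count)
                )
        return [path]
    raise ValueError(f"unknown export format {fmt!r} (graphml, csv_pair, cypher)")


def _cypher_str(value: str) -> str:
    return "'" + value.replace("\\", "\\\\").replace("'", "\\'") + "'"


def import_csv_pair(nodes_path: str | Path, edges_path: str | Path) -> KnowledgeGraph:
    """Reconstruct a graph from its csv_pair export (round-trip inverse)."""
    kg = KnowledgeGraph()
    with open(nodes_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != NODES_CSV_HEADER:
            raise ValueError(f"unexpected nodes.csv header {header}")
        for key, name, ntype in reader:
            kg.nodes[key] = KGNode(key, name, ntype)
    with open(edges_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != EDGES_CSV_HEADER:
            raise ValueError(f"unexpected edges.csv header {header}")
        for subj, rel, obj, support in reader:
            if subj not in kg.nodes or obj not in kg.nodes:
                raise ValueError(f"edge ({subj}, {rel}, {obj}) references a missing node")
            kg.edges[(subj, rel, obj)] = KGEdge(subj, obj, rel, int(support))
    return kg
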