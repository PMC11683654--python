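"""Compile ontology sources into the lookup structures that feed medical
knowledge into the extraction pipeline.

Three kinds of knowledge are compiled:

* a rare-disease lexicon (names + definitions, ORDO-style),
* a general concept lexicon of diseases and phenotypic abnormalities
  (Mondo-style), used for dictionary string matching, and
* an association index of (rare disease, occurrence frequency, phenotype)
  triples (HOOM-style), keyed by rare-disease name.

Two input dialects are accepted: OBO term stanzas (read through :mod:`obonet`)
and a compiled 4-column TSV (``id``, ``name``, pipe-separated ``synonyms``,
``definition``); associations use a 3-column TSV (``rare_disease``,
``frequency``, ``phenotype``).  Full OWL parsing is deliberately out of scope:
only names, synonyms, definitions and triples are consumed downstream.

All index keys are case-folded and whitespace-normalized; duplicate names are
resolved first-seen-wins with a logged warning; obsolete terms are excluded.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, TextIO

import obonet

from .normalize import normalize_name

logger = logging.getLogger(__name__)

CATEGORIES = ("rare_disease", "disease", "phenotype")

LEXICON_TSV_HEADER = ["id", "name", "synonyms", "definition"]
ASSOCIATION_TSV_HEADER = ["rare_disease", "frequency", "phenotype"]

_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class OntologyConcept:
    """One ontology term: an identifier, a preferred name, synonyms and an
    optional free-text definition, categorized as rare_disease, disease or
    phenotype."""

    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    definition: str = ""
    category: str = "disease"

    def __post_init__(self) -> None:
        if not self.preferred_name:
            raise ValueError(f"concept {self.concept_id!r}: empty preferred name")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"concept {self.concept_id!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )
        seen: set[str] = set()
        deduped = []
        for syn in self.synonyms:
            key = normalize_name(syn)
            if key and key not in seen:
                seen.add(key)
                deduped.append(syn)
        object.__setattr__(self, "synonyms", tuple(deduped))


@dataclass(frozen=True)
class AssociationTriple:
    """A (rare disease, occurrence-frequency qualifier, phenotype) triple."""

    rare_disease_name: str
    frequency_label: str
    phenotype_name: str

    def __post_init__(self) -> None:
        for f in ("rare_disease_name", "frequency_label", "phenotype_name"):
            if not getattr(self, f):
                raise ValueError(f"association triple: empty field {f!r}")


@dataclass
class KnowledgeBase:
    """Compiled lookup structures: two name->concept indexes plus the
    rare-disease->triples association index.  All keys are normalized."""

    rare_disease_lexicon: dict[str, OntologyConcept] = field(default_factory=dict)
    concept_lexicon: dict[str, OntologyConcept] = field(default_factory=dict)
    association_index: dict[str, list[AssociationTriple]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# source parsing

def _open_maybe(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8")
    return source


def _first_quoted(raw: str) -> str:
    """Pull the quoted payload out of an OBO ``def:``/``synonym:`` value."""
    m = _QUOTED.search(raw)
    return m.group(1).replace('\\"', '"') if m else raw.strip()


def _iter_obo_terms(source: str | Path | TextIO) -> Iterable[tuple[str, dict]]:
    """Yield (term_id, data) for non-obsolete stanzas of an OBO stream."""
    stream = _open_maybe(source)
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=False)
    except ValueError as exc:
        raise ValueError(f"unparseable OBO source: {exc}") from exc
    for term_id, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            continue
        yield term_id, data


def _iter_tsv_rows(
    source: str | Path | TextIO, header: list[str]
) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, row) for a compiled-dialect TSV, validating the header."""
    stream = _open_maybe(source)
    reader = csv.reader(stream, delimiter="\t")
    first = next(reader, None)
    if first is None:
        return
    if [c.strip() for c in first] != header:
        raise ValueError(
            f"TSV dialect: expected header {header}, got {first} (line 1)"
        )
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        yield lineno, row


def _concepts_from_obo(
    source: str | Path | TextIO, category_for: Callable[[str, str], str]
) -> Iterable[OntologyConcept]:
    for term_id, data in _iter_obo_terms(source):
        name = data.get("name", "").strip()
        if not name:
            raise ValueError(f"OBO stanza {term_id!r}: missing name")
        synonyms = tuple(_first_quoted(s) for s in data.get("synonym", []))
        definition = _first_quoted(data["def"]) if "def" in data else ""
        yield OntologyConcept(
            concept_id=term_id,
            preferred_name=name,
            synonyms=synonyms,
            definition=definition,
            category=category_for(term_id, name),
        )


def _concepts_from_tsv(
    source: str | Path | TextIO, category_for: Callable[[str, str], str]
) -> Iterable[OntologyConcept]:
    for lineno, row in _iter_tsv_rows(source, LEXICON_TSV_HEADER):
        if len(row) != 4:
            raise ValueError(f"TSV line {lineno}: expected 4 columns, got {len(row)}")
        cid, name, syns, definition = (c.strip() for c in row)
        if not name:
            raise ValueError(f"TSV line {lineno}: empty name")
        synonyms = tuple(s.strip() for s in syns.split("|") if s.strip())
        yield OntologyConcept(
            concept_id=cid,
            preferred_name=name,
            synonyms=synonyms,
            definition=definition,
            category=category_for(cid, name),
        )


def _iter_concepts(source, dialect, category_for) -> Iterable[OntologyConcept]:
    if dialect == "obo":
        return _concepts_from_obo(source, category_for)
    if dialect == "tsv":
        return _concepts_from_tsv(source, category_for)
    raise ValueError(f"unknown ontology dialect {dialect!r} (expected 'obo' or 'tsv')")


def _index_concepts(
    concepts: Iterable[OntologyConcept], include_synonyms: bool
) -> dict[str, OntologyConcept]:
    index: dict[str, OntologyConcept] = {}
    for concept in concepts:
        keys = [concept.preferred_name]
        if include_synonyms:
            keys.extend(concept.synonyms)
        for key in keys:
            norm = normalize_name(key)
            if not norm:
                continue
            existing = index.get(norm)
            if existing is None:
                index[norm] = concept
            elif existing.concept_id != concept.concept_id:
                # first-seen concept wins; later conflicts are only logged
                logger.warning(
                    "duplicate lexicon key %r: keeping %s, ignoring %s",
                    norm, existing.concept_id, concept.concept_id,
                )
    return index


# ---------------------------------------------------------------------------
# public compile / lookup operations

def index_concepts(
    concepts: Iterable[OntologyConcept], include_synonyms: bool = True
) -> dict[str, OntologyConcept]:
    """Index in-memory concepts by normalized preferred name (and synonyms),
    with the same first-seen-wins tie rule as the compile operations."""
    return _index_concepts(concepts, include_synonyms)


def group_associations(triples: Iterable[AssociationTriple]) -> dict[str, list[AssociationTriple]]:
    """Group in-memory triples by normalized rare-disease name, preserving order."""
    index: dict[str, list[AssociationTriple]] = {}
    for t in triples:
        index.setdefault(normalize_name(t.rare_disease_name), []).append(t)
    return index


def _rare_disease_category(_cid: str, _name: str) -> str:
    return "rare_disease"


def default_concept_category(concept_id: str, _name: str) -> str:
    """Infer disease vs phenotype from the identifier prefix (HP -> phenotype)."""
    return "phenotype" if concept_id.upper().startswith("HP") else "disease"


def compile_rare_disease_lexicon(
    source: str | Path | TextIO,
    dialect: str = "obo",
    *,
    include_synonyms: bool = True,
) -> dict[str, OntologyConcept]:
    """Compile an ORDO-style source into a name->concept index.

    Every non-obsolete term is indexed under its preferred name and (by
    default) each synonym; all concepts are categorized ``rare_disease`` and
    carry their definition when the source provides one.
    """
    return _index_concepts(
        _iter_concepts(source, dialect, _rare_disease_category), include_synonyms
    )


def compile_concept_lexicon(
    source: str | Path | TextIO,
    dialect: str = "obo",
    *,
    include_synonyms: bool = True,
    category_for: Callable[[str, str], str] = default_concept_category,
) -> dict[str, OntologyConcept]:
    """Compile a Mondo-style source of disease and phenotype concepts into the
    dictionary used for string matching."""
    return _index_concepts(
        _iter_concepts(source, dialect, category_for), include_synonyms
    )


def compile_association_index(
    source: str | Path | TextIO, dialect: str = "tsv"
) -> dict[str, list[AssociationTriple]]:
    """Group HOOM-style (rare disease, frequency, phenotype) rows by
    case-folded rare-disease name, preserving input order within a group.

    Rows missing any of the three fields are skipped with a warning.  The OBO
    dialect does not carry triples, so only ``tsv`` is accepted.
    """
    if dialect != "tsv":
        raise ValueError(
            f"association sources use the 'tsv' dialect, got {dialect!r}"
        )
    index: dict[str, list[AssociationTriple]] = {}
    for lineno, row in _iter_tsv_rows(source, ASSOCIATION_TSV_HEADER):
        if len(row) != 3:
            raise ValueError(f"TSV line {lineno}: expected 3 columns, got {len(row)}")
        disease, freq, phenotype = (c.strip() for c in row)
        if not (disease and freq and phenotype):
            logger.warning("association TSV line %d: missing field, skipped", lineno)
            continue
        triple = AssociationTriple(disease, freq, phenotype)
        index.setdefault(normalize_name(disease), []).append(triple)
    return index


def lookup_rare_disease(kb: KnowledgeBase, name: str) -> OntologyConcept | None:
    """Case-insensitive exact lookup against rare-disease preferred names and
    synonyms; ``None`` when no key matches (absence is a value, not an error)."""
    return kb.rare_disease_lexicon.get(normalize_name(name))


def lookup_concept(kb: KnowledgeBase, name: str) -> OntologyConcept | None:
    return kb.concept_lexicon.get(normalize_name(name))


def lookup_associations(kb: KnowledgeBase, rare_disease_name: str) -> list[AssociationTriple]:
    """Triples stored for a rare-disease name; empty list when absent."""
    return list(kb.association_index.get(normalize_name(rare_disease_name), []))


def build_knowledge_base(
    ordo_source=None,
    mondo_source=None,
    hoom_source=None,
    *,
    dialect: str = "obo",
    association_dialect: str = "tsv",
    include_synonyms: bool = True,
) -> KnowledgeBase:
    """Convenience constructor compiling all three sources in one call."""
    kb = KnowledgeBase()
    if ordo_source is not None:
        kb.rare_disease_lexicon = compile_rare_disease_lexicon(
            ordo_source, dialect, include_synonyms=include_synonyms
        )
    if mondo_source is not None:
        kb.concept_lexicon = compile_concept_lexicon(
            mondo_source, dialect, include_synonyms=include_synonyms
        )
    if hoom_source is not None:
        kb.association_index = compile_association_index(
            hoom_source, association_dialect
        )
    return kb


# ---------------------------------------------------------------------------
# compiled-dialect writers (used by the compile-kb CLI and the fixture generator)

def write_lexicon_tsv(concepts: Iterable[OntologyConcept], out: TextIO) -> None:
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(LEXICON_TSV_HEADER)
    for c in concepts:
        writer.writerow([c.concept_id, c.preferred_name, "|".join(c.synonyms), c.definition])


def write_associations_tsv(triples: Iterable[AssociationTriple], out: TextIO) -> None:
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(ASSOCIATION_TSV_HEADER)
    for t in triples:
        writer.writerow([t.rare_disease_name, t.frequency_label, t.phenotype_name])


def unique_concepts(index: dict[str, OntologyConcept]) -> list[OntologyConcept]:
    """Distinct concepts of an index in first-key order (an index maps many
    keys to one concept)."""
    seen: set[str] = set()
    out = []
    for concept in index.values():
        if concept.concept_id not in seen:
            seen.add(concept.concept_id)
            out.append(concept)
    return out
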