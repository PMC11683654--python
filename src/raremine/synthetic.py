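"""Synthetic mini-ontologies, gold-annotated corpora, and oracle states.

The generator makes the whole pipeline testable offline with analytically
known outcomes: it synthesizes a small rare-disease ontology (names,
definitions, synonyms), a disease/phenotype concept lexicon, association
triples, and multi-paragraph documents whose gold entities and relations are
embedded with exact character spans.  The deterministic mock backend answers
stage prompts from this gold, so with zero corruption the pipeline's output
is exactly the gold annotation and every metric is 100.0; with seeded
Bernoulli corruption the expected metrics have closed forms (for example,
expected entity recall 1 − entity_drop_p).

Default type proportions mirror a realistically skewed corpus: roughly a
third of entity occurrences are rare diseases, 40% symptoms and signs, 15%
diseases and around a tenth anaphors; the relation mix is dominated by
"produces" with small shares of the classification, acronym and synonym
relations.

Two generator guarantees keep the zero-corruption fixed point exact: every
gold entity participates in at least one relation (so calibration, whose
premise is that relationless entities are spurious, is the identity on
gold), and relation keys (subject name, type, object name) are unique within
a document (the pipeline collapses duplicates by that key).  Documents also
embed negation-bearing sentences ("There is no evidence of X") whose term is
in the lexicon but deliberately absent from gold, exercising negation
detection end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .corpus_io import AnnotatedDocument, EntityMention, RelationInstance
from .ontology_kb import (
    AssociationTriple,
    KnowledgeBase,
    OntologyConcept,
    group_associations,
    index_concepts,
    write_associations_tsv,
    write_lexicon_tsv,
)

_DEFAULT_RELATION_MIX = {
    "produces": 0.794,
    "increases_risk_of": 0.039,
    "is_a": 0.118,
    "is_acron": 0.035,
    "is_synon": 0.014,
}

_FREQUENCIES = ("very frequent", "frequent", "occasional", "rare")
_ANAPHOR_SURFACES = ("This disease", "This condition", "This disorder", "This syndrome")
_PHENO_SUFFIXES = ("swelling", "pain", "rash", "stiffness", "tremor")
_RD_SUFFIXES = ("syndrome", "disease", "disorder", "deficiency")

_SYLLABLES = [
    c + v for c in "bdfglkmnprstvz" for v in ("a", "e", "i", "o", "u")
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study: ontology sizes, corpus shape, and
    the rates controlling anaphors, cross-boundary relations and negation."""

    n_rare_diseases: int = 30
    n_diseases: int = 12
    n_phenotypes: int = 40
    n_docs: int = 20
    entities_per_doc: tuple[int, int] = (4, 10)
    relation_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RELATION_MIX)
    )
    anaphor_rate: float = 0.3  # chance of an anaphor follow-up per rare-disease fact
    cross_boundary_rate: float = 0.2  # chance the fact after a paragraph break spans it
    negation_rate: float = 0.15  # chance of a negated non-gold lexicon mention per fact
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("anaphor_rate", "cross_boundary_rate", "negation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.relation_mix.values()) - 1.0) > 1e-9:
            raise ValueError("relation_mix must sum to 1")
        if min(self.n_rare_diseases, self.n_diseases, self.n_phenotypes, self.n_docs) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class Corruption:
    """Seeded Bernoulli corruption rates applied by the mock backend."""

    entity_drop_p: float = 0.0
    type_confuse_p: float = 0.0
    relation_drop_p: float = 0.0
    spurious_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("entity_drop_p", "type_confuse_p", "relation_drop_p", "spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class OracleState:
    """Gold answers indexed by document, plus corruption and seed — the state
    the mock backend answers from."""

    gold: dict[str, AnnotatedDocument]
    corruption: Corruption = field(default_factory=Corruption)
    seed: int = 0


@dataclass
class OntologyFixture:
    rare_diseases: list[OntologyConcept]
    diseases: list[OntologyConcept]
    phenotypes: list[OntologyConcept]
    triples: list[AssociationTriple]
    #: acronym and synonym surface per rare-disease id, for corpus generation
    acronyms: dict[str, str] = field(default_factory=dict)
    alt_names: dict[str, str] = field(default_factory=dict)

    @property
    def concepts(self) -> list[OntologyConcept]:
        return self.diseases + self.phenotypes

    def knowledge_base(self, include_synonyms: bool = True) -> KnowledgeBase:
        return KnowledgeBase(
            rare_disease_lexicon=index_concepts(self.rare_diseases, include_synonyms),
            concept_lexicon=index_concepts(self.concepts, include_synonyms),
            association_index=group_associations(self.triples),
        )

    def write_tsv(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ordo": out_dir / "ordo.tsv",
            "mondo": out_dir / "mondo.tsv",
            "hoom": out_dir / "hoom.tsv",
        }
        with open(paths["ordo"], "w", encoding="utf-8") as fh:
            write_lexicon_tsv(self.rare_diseases, fh)
        with open(paths["mondo"], "w", encoding="utf-8") as fh:
            write_lexicon_tsv(self.concepts, fh)
        with open(paths["hoom"], "w", encoding="utf-8") as fh:
            write_associations_tsv(self.triples, fh)
        return paths

    def write_obo(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"ordo": out_dir / "ordo.obo", "mondo": out_dir / "mondo.obo"}
        _write_obo(self.rare_diseases, paths["ordo"])
        _write_obo(self.concepts, paths["mondo"])
        return paths


def _write_obo(concepts: list[OntologyConcept], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: raremine-synthetic\n")
        for c in concepts:
            fh.write(f"\n[Term]\nid: {c.concept_id}\nname: {c.preferred_name}\n")
            if c.definition:
                fh.write(f'def: "{c.definition}" [synthetic]\n')
            for syn in c.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')


# ---------------------------------------------------------------------------
# ontology generation

def _pseudoword(rng: random.Random, used: set[str]) -> str:
    while True:
        word = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(3, 4)))
        if word not in used:
            used.add(word)
            return word


def generate_ontology_fixture(spec: FixtureSpec) -> OntologyFixture:
    """Synthesize pronounceable, unique concept names, definitions, synonyms,
    acronyms and association triples; byte-deterministic per seed."""
    rng = random.Random(f"ontology:{spec.seed}")
    used_words: set[str] = set()
    used_acronyms: set[str] = set()

    rare_diseases: list[OntologyConcept] = []
    acronyms: dict[str, str] = {}
    alt_names: dict[str, str] = {}
    for i in range(spec.n_rare_diseases):
        base = _pseudoword(rng, used_words)
        suffix = _RD_SUFFIXES[i % len(_RD_SUFFIXES)]
        name = f"{base.capitalize()} {suffix}"
        cid = f"ORPHA:{1000 + i}"
        acronym = (base[:3] + suffix[0]).upper()
        while acronym in used_acronyms:
            acronym += rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        used_acronyms.add(acronym)
        alt = f"{_pseudoword(rng, used_words).capitalize()} {_RD_SUFFIXES[(i + 2) % len(_RD_SUFFIXES)]}"
        rare_diseases.append(
            OntologyConcept(
                concept_id=cid,
                preferred_name=name,
                synonyms=(alt,),
                definition=f"{name} is a synthetic rare disease concept ({cid}).",
                category="rare_disease",
            )
        )
        acronyms[cid] = acronym
        alt_names[cid] = alt

    diseases = []
    for i in range(spec.n_diseases):
        base = _pseudoword(rng, used_words)
        name = f"{base} disease" if rng.random() < 0.5 else base
        cid = f"MONDO:{7000 + i}"
        diseases.append(
            OntologyConcept(
                concept_id=cid,
                preferred_name=name,
                definition=f"{name} is a synthetic disease concept ({cid}).",
                category="disease",
            )
        )

    phenotypes = []
    for i in range(spec.n_phenotypes):
        base = _pseudoword(rng, used_words)
        name = f"{base} {rng.choice(_PHENO_SUFFIXES)}" if rng.random() < 0.3 else base
        cid = f"HP:{i:07d}"
        phenotypes.append(
            OntologyConcept(
                concept_id=cid,
                preferred_name=name,
                definition=f"{name} is a synthetic phenotype concept ({cid}).",
                category="phenotype",
            )
        )

    triples = []
    if phenotypes:
        for rd in rare_diseases:
            for p in rng.sample(phenotypes, min(rng.randint(1, 5), len(phenotypes))):
                triples.append(
                    AssociationTriple(rd.preferred_name, rng.choice(_FREQUENCIES), p.preferred_name)
                )
    return OntologyFixture(rare_diseases, diseases, phenotypes, triples, acronyms, alt_names)


# ---------------------------------------------------------------------------
# corpus generation

class _DocBuilder:
    """Incremental text assembly tracking exact mention offsets."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.text = ""
        self.entities: list[EntityMention] = []
        self.relations: list[RelationInstance] = []
        self._n = 0
        self._fresh_paragraph = True

    def new_paragraph(self) -> None:
        if self.text:
            self.text += "\n\n"
        self._fresh_paragraph = True

    def sentence(self, *parts) -> list[EntityMention]:
        """Append one sentence; parts are literals or (surface, type) pairs.
        Returns the mentions created, in order."""
        if not self._fresh_paragraph:
            self.text += " "
        self._fresh_paragraph = False
        created = []
        for part in parts:
            if isinstance(part, str):
                self.text += part
            else:
                surface, etype = part
                start = len(self.text)
                self.text += surface
                self._n += 1
                mention = EntityMention(surface, etype, (start, len(self.text)), f"T{self._n}")
                self.entities.append(mention)
                created.append(mention)
        return created

    def relate(self, rtype: str, subj: EntityMention, obj: EntityMention) -> None:
        self.relations.append(RelationInstance(rtype, subj.mention_id, obj.mention_id))

    def document(self) -> AnnotatedDocument:
        return AnnotatedDocument(self.doc_id, self.text, self.entities, self.relations)


def _pick_type(rng: random.Random, mix: dict[str, float]) -> str:
    roll = rng.random()
    acc = 0.0
    for rtype, p in mix.items():
        acc += p
        if roll < acc:
            return rtype
    return next(iter(mix))


_PRODUCES_TEMPLATES = (
    ("Patients with ", 0, " often develop ", 1, "."),
    ("Individuals affected by ", 0, " commonly present with ", 1, "."),
    ("Reports describe ", 1, " among people living with ", 0, "."),
)


def _emit_produces(builder, rng, subj_spec, obj_spec):
    template = rng.choice(_PRODUCES_TEMPLATES)
    parts = [subj_spec if p == 0 else obj_spec if p == 1 else p for p in template]
    created = builder.sentence(*parts)
    # created order follows the template; map back to subject/object
    by_surface = {m.surface: m for m in created}
    return by_surface[subj_spec[0]], by_surface[obj_spec[0]]


def generate_corpus(
    spec: FixtureSpec, ontology: OntologyFixture
) -> list[AnnotatedDocument]:
    """Generate multi-paragraph gold documents from the ontology fixture.

    Each document embeds relation-bearing "fact" sentences drawn from the
    relation mix, anaphor follow-up sentences after rare-disease facts at
    ``anaphor_rate`` (with gold anaphora links to the nearest antecedent),
    negated non-gold lexicon mentions at ``negation_rate``, and, at each
    paragraph break with probability ``cross_boundary_rate``, a relation
    whose two mentions fall in different paragraphs.  Deterministic per seed.
    """
    docs = []
    for d in range(spec.n_docs):
        rng = random.Random(f"corpus:{spec.seed}:{d}")
        docs.append(_generate_document(spec, ontology, rng, f"D{d:04d}"))
    return docs


def _generate_document(
    spec: FixtureSpec, ontology: OntologyFixture, rng: random.Random, doc_id: str
) -> AnnotatedDocument:
    builder = _DocBuilder(doc_id)
    rd_pool = rng.sample(ontology.rare_diseases, len(ontology.rare_diseases))
    disease_pool = rng.sample(ontology.diseases, len(ontology.diseases))
    pheno_pool = rng.sample(ontology.phenotypes, len(ontology.phenotypes))
    target = rng.randint(*spec.entities_per_doc)
    anaphor_cycle = 0
    facts_emitted = 0
    breaks_planned = max(1, target // 6)
    next_break_at = 2  # facts before the first paragraph break

    builder.new_paragraph()
    failures = 0
    while len(builder.entities) < target and failures < 50:
        crossing = False
        if facts_emitted == next_break_at and breaks_planned > 0:
            breaks_planned -= 1
            next_break_at = facts_emitted + 2
            crossing = rng.random() < spec.cross_boundary_rate
            if not crossing:
                builder.new_paragraph()
        rtype = _pick_type(rng, spec.relation_mix)
        emitted = _emit_fact(spec, ontology, builder, rng, rtype,
                             rd_pool, disease_pool, pheno_pool, crossing, anaphor_cycle)
        if emitted is None:
            failures += 1
            if not (rd_pool or disease_pool) or not pheno_pool:
                break  # pools exhausted
            continue
        failures = 0
        facts_emitted += 1
        anaphor_cycle = emitted
    return builder.document()


def _emit_fact(
    spec, ontology, builder, rng, rtype, rd_pool, disease_pool, pheno_pool,
    crossing: bool, anaphor_cycle: int,
) -> int | None:
    """Render one fact sentence (plus optional anaphor follow-up and negation
    sentence).  Returns the updated anaphor cycle counter, or None when the
    concept pools cannot support the requested relation type."""
    rd = rd_pool.pop() if rd_pool else None

    def give_up():
        if rd is not None:
            rd_pool.append(rd)
        return None

    if rtype == "produces" or crossing:
        subj = rd
        subj_type = "rare_disease"
        if subj is None or (not crossing and rng.random() < 0.3):
            if disease_pool:
                subj = disease_pool.pop()
                subj_type = "disease"
                if rd is not None:
                    rd_pool.append(rd)
                    rd = None
        if subj is None or not pheno_pool:
            return give_up()
        obj = pheno_pool.pop()
        if crossing:
            builder.sentence(
                "Clinicians frequently encounter ", (subj.preferred_name, subj_type),
                " in practice.",
            )
            subj_mention = builder.entities[-1]
            builder.new_paragraph()
            builder.sentence(
                "Affected individuals often develop ",
                (obj.preferred_name, "symptom_and_sign"), " early in the course.",
            )
            obj_mention = builder.entities[-1]
        else:
            subj_mention, obj_mention = _emit_produces(
                builder, rng, (subj.preferred_name, subj_type),
                (obj.preferred_name, "symptom_and_sign"),
            )
        builder.relate("produces", subj_mention, obj_mention)
        anaphor_host = subj_mention if subj_type == "rare_disease" else None
    elif rtype == "increases_risk_of":
        if rd is None or not disease_pool:
            return give_up()
        obj = disease_pool.pop()
        ments = builder.sentence(
            "The presence of ", (rd.preferred_name, "rare_disease"),
            " increases the risk of ", (obj.preferred_name, "disease"), ".",
        )
        builder.relate("increases_risk_of", ments[0], ments[1])
        anaphor_host = ments[0]
    elif rtype == "is_a":
        if rd is None or not disease_pool:
            return give_up()
        obj = disease_pool.pop()
        ments = builder.sentence(
            (rd.preferred_name, "rare_disease"), " is a form of ",
            (obj.preferred_name, "disease"), ".",
        )
        builder.relate("is_a", ments[0], ments[1])
        anaphor_host = ments[0]
    elif rtype == "is_acron":
        if rd is None:
            return give_up()
        acronym = ontology.acronyms[rd.concept_id]
        ments = builder.sentence(
            (acronym, "rare_disease"), " is an acronym for ",
            (rd.preferred_name, "rare_disease"), ".",
        )
        builder.relate("is_acron", ments[0], ments[1])
        anaphor_host = ments[1]
    elif rtype == "is_synon":
        if rd is None:
            return give_up()
        alt = ontology.alt_names[rd.concept_id]
        ments = builder.sentence(
            (rd.preferred_name, "rare_disease"), " is also known as ",
            (alt, "rare_disease"), ".",
        )
        builder.relate("is_synon", ments[0], ments[1])
        anaphor_host = ments[0]
    else:
        return give_up()

    if anaphor_host is not None and pheno_pool and rng.random() < spec.anaphor_rate:
        surface = _ANAPHOR_SURFACES[anaphor_cycle % len(_ANAPHOR_SURFACES)]
        anaphor_cycle += 1
        pheno = pheno_pool.pop()
        ments = builder.sentence(
            (surface, "anaphor"), " also produces ",
            (pheno.preferred_name, "symptom_and_sign"), ".",
        )
        builder.relate("anaphora", ments[0], anaphor_host)
        builder.relate("produces", ments[0], ments[1])

    if pheno_pool and rng.random() < spec.negation_rate:
        # a lexicon term in a negated context, deliberately absent from gold
        pheno = pheno_pool.pop()
        builder.sentence("There is no evidence of ", pheno.preferred_name, ".")
    return anaphor_cycle


def cross_boundary_relations(doc: AnnotatedDocument) -> list[RelationInstance]:
    """Relations whose two mentions fall in different paragraphs."""
    import re

    starts = [0]
    for m in re.finditer(r"\n[ \t]*\n+", doc.text):
        starts.append(m.end())

    def para_of(pos: int) -> int:
        idx = 0
        for i, s in enumerate(starts):
            if pos >= s:
                idx = i
        return idx

    out = []
    for rel in doc.relations:
        subj = doc.mention_by_id(rel.subject_ref)
        obj = doc.mention_by_id(rel.object_ref)
        if subj and obj and subj.span and obj.span:
            if para_of(subj.span[0]) != para_of(obj.span[0]):
                out.append(rel)
    return out


def write_corpus(docs: list[AnnotatedDocument], out_dir: str | Path) -> list[Path]:
    """Write documents as BRAT standoff (.txt + .ann) pairs."""
    from .corpus_io import write_standoff

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc in docs:
        txt = out_dir / f"{doc.doc_id}.txt"
        ann = out_dir / f"{doc.doc_id}.ann"
        with open(txt, "w", encoding="utf-8") as t, open(ann, "w", encoding="utf-8") as a:
            write_standoff(doc, t, a)
        paths.extend([txt, ann])
    return paths


def build_oracle(
    corpus: list[AnnotatedDocument],
    corruption: Corruption | None = None,
    seed: int = 0,
) -> OracleState:
    """Index gold answers by document for the mock backend."""
    return OracleState(
        gold={doc.doc_id: doc for doc in corpus},
        corruption=corruption or Corruption(),
        seed=seed,
    )
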