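import io
import logging

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from raremine import synthetic as syn
from raremine.llm_runtime import MockBackend
from raremine.ontology_kb import (
    compile_association_index,
    compile_concept_lexicon,
    compile_rare_disease_lexicon,
    KnowledgeBase,
)

# the per-item drop/filter warnings are part of the contract but drown out
# test output under corruption
logging.getLogger("raremine.pipeline").setLevel(logging.ERROR)
logging.getLogger("raremine.llm_runtime").setLevel(logging.ERROR)


ORDO_OBO = """format-version: 1.2
ontology: test-ordo

[Term]
id: ORPHA:2059
name: Fryns syndrome
def: "A rare multiple congenital malformation syndrome." [test]
synonym: "Fryns anomaly" EXACT []

[Term]
id: ORPHA:3280
name: Giant cell myocarditis
def: "A rare inflammatory cardiomyopathy." [test]

[Term]
id: ORPHA:9999
name: Retired entity
is_obsolete: true
"""

MONDO_OBO = """format-version: 1.2
ontology: test-mondo

[Term]
id: MONDO:0004992
name: cancer
def: "A disease of uncontrolled cell growth." [test]

[Term]
id: HP:0012378
name: fatigue
def: "A subjective feeling of tiredness." [test]

[Term]
id: HP:0000988
name: rash
synonym: "skin rash" EXACT []
synonym: "exanthem" EXACT []

[Term]
id: HP:0011675
name: abnormal heart rate

[Term]
id: HP:0001626
name: heart
"""

HOOM_TSV = (
    "rare_disease\tfrequency\tphenotype\n"
    "Fryns syndrome\tvery frequent\tfatigue\n"
    "Fryns syndrome\toccasional\trash\n"
    "Giant cell myocarditis\tfrequent\tabnormal heart rate\n"
)


@pytest.fixture
def ordo_lexicon():
    return compile_rare_disease_lexicon(io.StringIO(ORDO_OBO), "obo")


@pytest.fixture
def mondo_lexicon():
    return compile_concept_lexicon(io.StringIO(MONDO_OBO), "obo")


@pytest.fixture
def hoom_index():
    return compile_association_index(io.StringIO(HOOM_TSV), "tsv")


@pytest.fixture
def tiny_kb(ordo_lexicon, mondo_lexicon, hoom_index):
    return KnowledgeBase(
        rare_disease_lexicon=ordo_lexicon,
        concept_lexicon=mondo_lexicon,
        association_index=hoom_index,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 10-document synthetic study with its ontology, knowledge base, and
    zero-corruption oracle backend."""
    spec = syn.FixtureSpec(n_docs=10, seed=7)
    ontology = syn.generate_ontology_fixture(spec)
    docs = syn.generate_corpus(spec, ontology)
    kb = ontology.knowledge_base()
    backend = MockBackend(syn.build_oracle(docs, seed=1))
    return spec, ontology, docs, kb, backend
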