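# Methods

This note documents the models and procedures `raremine` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Pipeline model

The extraction task: given a medical text *T*, produce entities
*E = {E1 … En}* over the four-type system (`rare_disease`, `disease`,
`symptom_and_sign`, `anaphor`) and relations *R* over the six-type system
(`produces`, `increases_risk_of`, `is_a`, `is_acron`, `is_synon`,
`anaphora`), then a knowledge graph over the aligned names. An anaphor is a
pronoun or nominal phrase ("this disease") whose antecedent must be a rare
disease.

### Preprocessing

Documents are segmented at natural paragraph boundaries (one or more blank
lines) so each segment stays **under `segment.max_tokens` (default 2000)**
— sized for an 8000-token model context with roughly 1000 instruction
tokens. An over-budget paragraph is re-packed at sentence boundaries
(period/question/exclamation + whitespace); an over-budget sentence is
hard-wrapped at the token level with a warning. Segment character spans tile
the document, so segmentation is loss-free and deterministic.

The token counter is configurable: `whitespace` (the rule-based default in
environments without a byte-pair encoder; 5 words count 5 tokens) or
`tiktoken:<encoding>` when that library is importable (`auto` prefers
byte-pair and falls back to whitespace). Counts are deterministic per spec.

Because relations occasionally straddle a paragraph boundary, one **bridge
window** per adjacent boundary (default `segment.bridge_tokens` = 1000,
half drawn from each side, clipped at the flanking segments) is used for a
second relation-extraction pass. Bridge windows re-extract *relations only*;
the entities fed to the bridge call are those from the two flanking segments
whose spans fall inside the window. Duplicate relations collapse by
(subject, type, object).

### Ontology compilation

Three knowledge sources are compiled: a rare-disease lexicon
(name/synonym → concept with definition), a general disease/phenotype
lexicon used as the string-matching dictionary, and an association index of
(rare disease, frequency, phenotype) triples keyed by rare-disease name.
Accepted dialects are OBO term stanzas (via `obonet`) and a compiled
4-column TSV (`id`, `name`, pipe-separated `synonyms`, `definition`;
associations: `rare_disease`, `frequency`, `phenotype`). Full OWL parsing is
out of scope — only names, definitions, synonyms and triples are consumed.
Index keys are case-folded and whitespace-normalized uniformly (the same
normalization used at graph alignment and in the scorer). Duplicate names
resolve first-seen-wins with a logged warning; obsolete terms are excluded;
synonym indexing can be disabled. Because the TSV dialect carries no
category column, the general lexicon's disease-vs-phenotype category is
inferred from the identifier prefix (`HP` → phenotype), overridable by
argument.

### Staged entity extraction

Step 1 (dictionary): case-insensitive, word-boundary, longest-match-wins,
non-overlapping string matching against the concept lexicon; each hit
carries the concept's definition. Negation detection flags hits preceded by
a cue within `negation.window_tokens` (default 5) tokens with no intervening
period/semicolon; the shipped cue list (no, not, without, denies, …,
lack of) is a user-extendable one-cue-per-line file. Negated candidates are
**kept and flagged**, not dropped — the flag is surfaced to the model, which
decides. This is deliberately not a full NegEx/ConText implementation (no
post-position cues, uncertainty, or experiencer handling).

Step 2 (extract more terms): the passage and the flagged dictionary hits go
to the model, which returns additional terms and the passage's anaphors.

Step 3 (extract entities): candidates, anaphors, exemplars, and rare-disease
knowledge (name + definition for every candidate that hits the rare-disease
lexicon) go to the model, which returns typed entities. **Step-3 output is
authoritative** — dictionary matches are hints, not guarantees. Entities
typed outside the four-type system are dropped with a warning rather than
coerced; silent coercion would corrupt the confusion matrices.

### Relation extraction and calibration

All extracted entities (with types) are fed to the model together with the
association triples of any rare-disease entity present. Returned relations
are filtered: both endpoints must be among the provided entities, the type
must be in the six-type system, and an anaphora relation must have a
rare-disease antecedent.

Calibration rests on the observation that entities with no relations are
disproportionately generic or falsely ascribed terms (the bare word
"disorder", say). Three modes: `rule` drops zero-relation entities; `llm`
asks the model to confirm a retained list (constrained to a subset of the
input); `both` (default) applies the rule, then the model on the survivors.
Relations referencing dropped entities are removed. Calibration never adds
entities.

### Prompts

Each stage's prompt is assembled in a fixed section order — stage marker,
task description, type definitions, notice, exemplars, JSON slots, output
format — from an editable plain-text template. The **notice** block is the
hand-tunable guideline text correcting known model misinterpretations; it,
the exemplars, and the injected knowledge are the three ablation axes, and
toggles only add or remove whole sections. Exemplars are a seeded uniform
sample of k = 5 training documents serialized as gold input/output pairs;
the relation stage reuses the same sampled documents. The instruction budget
is ~1000 tokens on top of the passage; over budget, exemplars are dropped
from the end, then knowledge slots truncated — the passage is never cut.

The first line of every prompt is a machine-readable stage marker
(`<<raremine stage=… doc=… span=a-b bridge=0|1>>`). A live model treats it
as instruction text; the mock backend uses it for routing. Slot payloads are
fenced JSON blocks tagged `[slot:<name>]` so the mock can recover them; an
empty slot renders an explicit "(none found)" marker.

### Backends and payload parsing

Backends implement a one-method contract (`respond(prompt) → text`).
`complete()` refuses prompts that cannot fit the context window
(`max_context_tokens`, default 8000, minus a 1000-token response reserve),
retries transient failures up to `retry_limit`, and records token counts and
latency. Temperature defaults to 0 for the most stable output. JSON payloads
are recovered by a repair ladder: whole-text parse, fenced-block extraction,
raw decode from the first brace, then bracket-balancing truncation repair;
expected list keys are coerced to `[]` when missing, and anything else
missing is a schema error naming the keys. No module outside the backend
layer performs I/O to a model.

The mock backend answers each stage from gold annotations restricted to the
marker's character window, perturbed by per-item Bernoulli corruption
(entity drop, type confusion, relation drop, spurious insertion) seeded by a
stable hash of (oracle seed, document, stage, window) — byte-deterministic
given (state, prompt). The calibration stage echoes the candidate list
parsed from the prompt. Mock entity output includes passage-relative
character offsets (the output schema requests them; live backends may omit
them, in which case span-dependent steps degrade gracefully to name-level
behavior).

### Knowledge graph

Names are aligned by lowercase matching (case-fold + trim + collapse
whitespace — idempotent). Anaphoric relations are rewritten to their
antecedent's name; with multiple antecedent links for one anaphor name the
textually nearest preceding antecedent wins (with a warning), and unlinked
anaphors are removed along with their relations. Nodes merge by normalized
name keeping the first-seen display form; a name seen with conflicting types
takes rare_disease over disease over symptom_and_sign (logged). Duplicate
triples increment a support count. Isolated nodes are excluded — consistent
with calibration's premise — though the underlying results retain them.
Exports: GraphML, a Neo4j-bulk-import-friendly nodes.csv/edges.csv pair
(round-trip importable), and Cypher MERGE statements. Managing a live graph
database is out of scope.

## Evaluation

Occurrence-level multiset matching per document, by (normalized name, type)
for entities and (normalized subject, type, normalized object) for
relations; replicated mentions count per occurrence; relation scoring does
not condition on whether the endpoint entities were themselves scored
correct. Matching is exact-after-normalization — no fuzzy or span-overlap
credit. With equality-keyed pairing, greedy matching equals the optimal
bipartite matching (per key, min of the two multiplicities), which the test
suite verifies against an independent maximum-matching oracle.

Micro-averaged P/R/F1 per type and overall; the overall row is the
arithmetic mean of the entity-overall and relation-overall values (the F1
rule stated for the headline metric, mirrored for P and R so the overall row
is reproducible arithmetic). Internal math is unrounded; reports round
half-up to one decimal. An empty prediction set reports precision 0 with an
explicit flag. Confusion matrices exclude replicated entities (per-document
name-level sets), with `Error` on the predicted axis for falsely extracted
items and on the true axis for gold items not extracted.

## Synthetic data: what it emulates, and what it does not

The generator synthesizes a mini-ontology (pronounceable unique pseudoword
names, definitions, one synonym and one acronym per rare disease, 1–5
association triples each) and multi-paragraph documents built from
relation-bearing template sentences, with exact gold spans. Defaults mirror
a realistically skewed corpus: entity occurrences roughly one-third rare
diseases, 40% symptoms/signs, 15% diseases, ~10% anaphors; the relation mix
is dominated by `produces` (~0.79) with small shares of `is_a` (0.12),
`increases_risk_of` (0.04), `is_acron` (0.035) and `is_synon` (0.014).
Anaphor follow-up sentences are inserted after rare-disease facts at
`anaphor_rate` (default 0.3 per rare-disease fact, yielding roughly the
target occurrence share), with gold anaphora links to the nearest
antecedent. Negation-bearing sentences ("There is no evidence of X", X in
the lexicon but absent from gold) appear at `negation_rate` = 0.15 to
exercise negation detection. At each paragraph break, with probability
`cross_boundary_rate`, the next fact is rendered with its two mentions in
different paragraphs.

Two guarantees make outcomes analytic. Every gold entity participates in at
least one relation, so calibration is the identity on uncorrupted gold. And
relation keys (subject name, type, object name) are unique within a
document, so the pipeline's cross-segment deduplication cannot merge two
distinct gold relations. Consequently the zero-corruption mock is a fixed
point — the pipeline reproduces gold exactly, P = R = F1 = 100 — and under
entity-drop probability *p* the expected entity recall is 1 − *p* (binomial
standard error √(p(1−p)/n)) while a relation survives exactly when both its
endpoint names survive (≈ (1−p)² with per-document-unique names).

What the generator does **not** emulate: clinical-language variability,
paraphrase, hedging, nested or discontinuous mentions, boundary ambiguity,
cross-document coreference, and ontology noise (typos, near-synonyms).
Passing tests therefore demonstrate the correctness of the pipeline's
mechanics — segmentation, knowledge injection, parsing, filtering,
calibration, graph assembly, scoring — not the linguistic competence of any
live model on real text.

## Problem sizes and numerical choices

The test and acceptance studies use corpora of 20–100 documents with 4–12
entities per document (the corruption study uses 80 documents / ≥500 gold
occurrences so the 3-standard-error band around the expected recall is
±4–5 points). Synthetic documents are short, so studies that exercise
segmentation set the segment budget to ~30 whitespace tokens and the bridge
width to 600 — the same mechanism as the 2000/1000 defaults, scaled to the
document length. The corruption study runs calibration in `llm` mode (the
mock echoes its input) so the measured recall isolates the entity-drop
process; `both` mode would additionally drop entities orphaned by relation
loss, which is visible as a small extra recall dip when bridges are disabled
in the bridge-recovery study.

Ties and degenerate inputs: dataset splitting shuffles with a seeded RNG and
apportions sizes by largest remainder (earlier part wins remainder ties), so
1040 documents at 6:2:2 give exactly 624/208/208 and reproducibility is
per-seed; empty sources compile to empty indexes; an empty corpus evaluates
to an all-zero flagged report; division-by-zero in P/R/F1 reports 0.

## Known limitations

* The live OpenAI-compatible adapter is a thin shim and is exercised only
  through a stubbed transport in tests; no network I/O happens anywhere in
  the offline path.
* Name-level relation references (used when spans are absent) cannot
  distinguish two same-surface anaphors with different antecedents in one
  document; the nearest-antecedent heuristic covers the common case.
* The negation detector handles pre-position cues only.
* Entity normalization to ontology identifiers (entity linking) is out of
  scope beyond the knowledge-slot lookup.
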