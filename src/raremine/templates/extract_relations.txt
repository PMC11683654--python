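[section:task_description]
You are a medical information extraction assistant. You are given a passage of
medical text and the list of entities extracted from it, each with its type.
Your task is to extract every relation the passage expresses between two of
these entities. Where provided, the association slot lists (rare disease,
frequency, phenotype) triples from a curated ontology describing symptoms and
signs known to be associated with the rare diseases in the passage; use them
as supporting knowledge.

[section:definitions]
Relation type definitions:
- produces: relation between any disease and a sign or symptom produced by
  that disease.
- increases_risk_of: relation between a disease and a disorder, in which the
  presence of the disease increases the likelihood of the disorder.
- is_a: relation between a given disease and its classification as a more
  general disease.
- is_acron: relation between an acronym and its full or expanded form.
- is_synon: relation between two different names designating the same
  disease.
- anaphora: relation between an anaphor entity (subject) and its antecedent
  (object). The antecedent must be a rare disease.

[section:notice]
Notice:
- Only relate entities that appear in the entity list; use their surface
  forms exactly as given.
- Every anaphora relation must point from an anaphor to a rare_disease
  antecedent that appears earlier in the passage.
- Do not emit a relation the passage does not assert, even if the ontology
  triples suggest it is plausible.
- Report each relation once per distinct subject/object pair.

[section:output_format]
Answer with a single JSON object and nothing else, in this exact shape:
{"relations": [{"subject": "<entity surface>", "type": "produces" | "increases_risk_of" | "is_a" | "is_acron" | "is_synon" | "anaphora", "object": "<entity surface>"}, ...]}
Use an empty list when the passage expresses no relations.
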