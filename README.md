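# trialmatch

Explainable, rule-based matching of oncology patient records to phase 1
clinical-trial protocols.

Screening patients for early-phase oncology trials means reading free-text
clinic notes against free-text protocol eligibility sections — slow,
skilled work that scales badly. `trialmatch` is a prototype NLP pipeline
for the four eligibility criteria that gate most phase 1 oncology trials:

1. **Cancer type** (with metastatic status as a sub-variable), resolved
   against a Neoplasm-branch concept store in the shape of the NCI
   Thesaurus (root code C3262), with subtype reasoning over its is-a DAG;
2. **ECOG performance status** (0 = fully active … 4 = bed bound),
   extracted explicitly from "ECOG …" phrases or implicitly from
   functional-status language ("doing well", "wheelchair bound");
3. **Measurable disease** per RECIST 1.1 — a solid-organ lesion ≥ 1 cm or
   a lymph node ≥ 1.5 cm; bone lesions are never measurable;
4. **Genetic mutation**, matched by token overlap between the patient's
   molecular findings and the protocol's required gene list, with
   therapy-context filtering (`anti-HER2`, `VEGF-targeted` are treatments,
   not tumor genotypes).

Every pair of documents receives a matching score

```
score = n_criteria_met / n_criteria_required_by_protocol
```

and a decision: **match** iff `score > 0.5` (strictly). The system is
deliberately not a black box: each required criterion contributes one
evidence sentence naming both the patient finding and the protocol
requirement, so a clinician can audit — or overrule — every verdict.

The pipeline stages: document sectioning (Inclusion/Exclusion/body) and
rule-based sentence splitting; entity tagging via a built-in lexicon
tagger plus a JSON-lines plug-in contract for external NER taggers;
offset rectification (±40-character search) and merge of multi-tagger
output; Schwartz–Hearst abbreviation expansion; sentence-scope negation;
the four criterion extractors; scoring and report assembly.

Because no public corpus of phase 1 patient records exists, the package
includes a seeded synthetic-corpus generator (`trialmatch.synth`) that
renders narrative patient notes and sectioned protocols from structured
profiles, labels every pair with pipeline-independent gold logic, and can
plant the error modes that break rule-based matchers (undefined
abbreviations, gene synonyms, expression variants, negated distractors,
millimetre units) at controlled rates.

## Worked example

```python
from trialmatch.pipeline import build_resources, match_texts

res = build_resources()
patient = (
    "The patient is a 61-year-old woman with metastatic breast carcinoma. "
    "ECOG performance status: 2. "
    "CT imaging demonstrated a (2.1 x 1.4) cm lesion in the liver. "
    "Next-generation sequencing identified pathogenic alterations in BRCA1 and TP53."
)
protocol = """\
Inclusion Criteria:
- Histologically confirmed metastatic breast carcinoma.
- ECOG performance status 0-1.
- Measurable disease per RECIST v1.1.
- A known pathogenic mutation in any of the following genes: BRCA1, ATM.
Exclusion Criteria:
- Pregnancy or breastfeeding.
"""
print(match_texts(patient, protocol, res, patient_id="5", protocol_id="3").render_text())
```

prints

```
Patient 5 vs Protocol 3
Matching score: 0.75 (3 of 4 required criteria met)
Decision: match
  [cancer_type] evidence:
    Patient 5 has cancer type metastatic Breast Carcinoma which matches Protocol 3 which requires cancer type metastatic Breast Carcinoma
  [ecog] no evidence:
    Patient 5 has ECOG status [2] which does not match Protocol 3 which requires ECOG status of 0–1
  [measurable] evidence:
    Patient 5 has measurable disease which matches Protocol 3 which requires measurable disease
  [mutation] evidence:
    Patient 5 has genetic mutation [BRCA1] which matches Protocol 3 which requires a mutation in [ATM, BRCA1]
```

Three of four required criteria are met, so the score is 0.75 and the
pair is declared a match — yet the report also shows exactly why the
ECOG criterion fails, which is the information a human screener needs to
reject the pair.

## Command line

```bash
trialmatch synth --patients 12 --protocols 6 --seed 1 --out corpus/
trialmatch batch corpus/manifest.json --out preds.jsonl
trialmatch evaluate preds.jsonl corpus/gold_labels.csv --out metrics.json
trialmatch match corpus/P1.txt corpus/T1.txt
```

`evaluate` prints the confusion matrix and precision / sensitivity /
specificity / accuracy (percentages rounded half-up to two decimals).

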