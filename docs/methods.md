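# Methods

## The matching model

`trialmatch` treats patient-to-trial matching as four independent
criterion checks followed by a transparent aggregation rule. For a
patient record *p* and protocol *q*, each criterion *c* ∈ {cancer type,
ECOG, measurable disease, mutation} yields:

- `required(c, q)` — true iff the protocol's *inclusion* section produces
  at least one non-negated finding for *c*. This is the denominator rule:
  a protocol that never mentions ECOG does not test ECOG.
- `satisfied(c, p, q)` — defined only when required; per-criterion rules
  below.

The score is `n_met / n_required`, and the decision is **match** iff the
score strictly exceeds the threshold (default 0.5). When `n_required = 0`
the score is undefined and the pair is reported *indeterminate* — it is
excluded from evaluation counts rather than coerced to either class
(a config flag, `indeterminate_as_no_match`, restores a strictly binary
confusion matrix). Exclusion-section conflicts never enter the score;
they are emitted as flags for the human reviewer, because the score is
inclusion-driven and the reviewer, not the scorer, owns exclusion
decisions.

### Criterion rules

**Cancer type.** Disease-tagged mentions map to concepts through a
two-tier lookup (preferred names, then synonyms) after word-order-free
normalization (lowercase, punctuation stripped, words sorted). Generic
concepts — Malignant/Solid/Metastatic Neoplasm and the bare Neoplasm
root — are blocklisted: they say nothing about which trial fits. The
blocklist is code-level; name-level aliases route through the same codes.
A second pass combines an organ mention with a cancer mention in the same
sentence ("lung" + "adenocarcinoma" → "lung adenocarcinoma") and keeps
the more specific concept when it resolves. Metastatic status: a patient
is metastatic if a metastasis cue appears anywhere in the record (the
raw-token scan deliberately ignores negation — it is a crude,
high-recall rule); a protocol concept is metastatic only when cue and
concept share a sentence. The match test: some patient concept is a
subtype (reflexive, DAG-transitive) of some required concept, and if the
requirement is metastatic the patient must be too. Reflexivity matters:
a protocol requiring exactly the patient's diagnosis must match.

**ECOG.** Explicit extraction regexes the text around the literal
keyword `ECOG`, capturing an optional comparator (≤, <=, ≥, >=, =) and a
digit or digit range 0–4; digits outside 0–4 are skipped with a warning.
Protocols yield a requirement — a bare digit defaults to ≤ (the usual
protocol reading); patients yield a status interval. When a patient
record never says "ECOG", an implicit pass maps good-health phrases
("active", "doing well", …) to [0, 1] and poor-health phrases
("wheelchair bound", "bed bound", …) to [2, 4]; if both occur, the
mention latest in the record wins (clinical notes are roughly
chronological). Matching is conservative interval containment: the whole
patient interval must sit inside the requirement's admissible set, so an
implicit [0, 1] patient does *not* satisfy a 0-only requirement. The
conservatism trades recall for defensible evidence lines and is visible
in the report (implicit statuses are annotated as inferred).

**Measurable disease.** Lesion sizes parse from the renderings clinical
notes actually use — `(a x b) cm`, `(a x b x c) cm`, `a.b cm`, bare
`a cm`, and millimetre variants (converted to cm) — keeping the longest
dimension. Sites normalize through a config table into solid organ /
lymph node / bone; a size with no site word in its sentence is `unknown`
and never qualifies. RECIST 1.1 thresholds: solid organ ≥ 1.0 cm, lymph
node ≥ 1.5 cm, bone never measurable. The comparator is configurable
(≥ by default, strict > available) because usage in the field wavers
between "1 cm or above" and "greater than 1 cm"; the package standardises
on the inclusive RECIST reading. A protocol requires measurability iff
its inclusion section contains "measurable disease" or "measuring" and
does not mention "non-measurable disease"; when not required, all
patients qualify and the criterion leaves the denominator.

**Mutation.** Gene/mutation/DNA-tagged tokens are compared by
case-insensitive exact-string overlap. Tokens immediately preceded by
"anti-"/"anti " or followed by "-targeted"/" targeted" describe prior
therapies and are excluded. By default no synonym resolution is applied —
exact-token matching is the honest baseline, and its documented failure
modes (CHEK2 vs CHK2; "BRCA1 mut" vs BRCA1) are reproduced by the
synthetic confounders. Switching `synonym_table_enabled` on canonicalises
tokens through a small gene-synonym table before intersecting, which
removes exactly those failures.

### Preprocessing

All offsets are 0-based half-open character spans; a single convention
end-to-end prevents the offset drift that multi-tagger NER pipelines
suffer. External taggers plug in through a JSON-lines contract; the
built-in tagger is a longest-match-first, case-insensitive dictionary
scan over token n-grams (n ≤ 6) whose dictionary is generated from the
ontology plus organ/gene/metastasis tables. Before merging, every
mention is rectified: if its claimed span does not reproduce its surface,
the raw text is searched within ±40 characters of the claimed start
(case-sensitive first, then case-insensitive, nearest occurrence wins);
unfindable mentions are dropped. Mentions with identical rectified spans
merge into one mention carrying the union of (tag, tagger) pairs;
partially overlapping spans stay separate — exact-coincidence is the only
merge key with a defensible semantics.

Abbreviations are recovered Schwartz–Hearst style from `LONG FORM
(SHORT)` patterns (short form 2–10 chars, ≥ 50% uppercase letters, no
whitespace; right-to-left character matching with the first character
anchored to a word start), first definition wins, and every later use of
the short form is expanded before matching. An acronym never defined in
the document stays unexpanded — whatever the ontology then makes of it
(e.g. the lab value ALT resolving to Atypical Lipomatous Tumor) is a
real, documented failure mode of this system class, reproduced rather
than patched.

Negation is the simplified sentence-scope rule: any trigger phrase
("except for", "no evidence of", "without", …, all config-overridable)
negates every mention in its sentence. Scope direction is not modelled;
the sentence splitter is therefore deterministic and rule-based
(newlines; `.?!` + whitespace + uppercase; never inside parentheses or
after initials/known abbreviations) so that scoping is reproducible.

## The synthetic corpus

`trialmatch.synth` generates the study conditions: by default 12 patient
records × 6 protocols = 72 gold-labelled pairs per seed. Patient profiles
(cancer concept, metastatic flag, ECOG level and rendering mode, lesion
list, mutation list, prior-therapy genes) render into template-based
narrative notes; protocol profiles render into titled documents with
Inclusion/Exclusion sections, in bulleted or prose layout, with seeded
template variation ("ECOG performance status 0-1" vs "≤ 1"; RECIST
phrasing; prepositional vs combined cancer names). All randomness derives
from the corpus seed through independent per-document streams, so
bundles are byte-reproducible and enabling a confounder perturbs only the
documents that received it.

Gold labels are computed from the profiles alone — subtype via the
ontology's parent edges, interval containment for ECOG, RECIST
thresholds, mutation intersection with *true* synonym resolution — never
by running the extraction pipeline (enforced by a test that stubs the
pipeline out). A pair is gold-match iff every requirement the protocol
states is satisfied, mirroring how a physician reads eligibility.

The all-requirements gold rule and the majority-threshold score disagree
by construction on pairs where a strict majority but not all requirements
hold (that disagreement is precisely the false-positive mechanism the
report's evidence lines exist to catch). So that a confounder-free corpus
isolates *extraction* fidelity, the generator rejection-samples patients
until every pair is decisive — all requirements met, or at most half.
On such corpora the pipeline's decisions recover the gold labels exactly
(verified over multiple seeds in the acceptance tests); every residual
disagreement on a confounded corpus is then attributable to a planted
confounder.

Confounders (rates configurable per corpus): `undefined_abbrev` injects
an AST/ALT liver-function criterion into a protocol (spurious tumor
concept → spurious cancer requirement); `negated_cancer` adds a negated
cancer distractor sentence to a patient; `gene_synonym_swap` renders a
mutation under its synonym (CHEK2 for CHK2); `expression_variant` renders
"GENE mut" instead of the bare symbol; `size_in_mm` switches lesion sizes
to millimetres (handled correctly by the parser — it verifies unit
robustness rather than planting an error). Gold labels never change under
confounding; only renderings do.

What the generator does *not* emulate: the discourse structure, noise and
redundancy of real clinical prose; lab-value and prior-treatment-line
criteria; hedged or uncertain findings; OCR artifacts. Passing the
clean-corpus test therefore shows the pipeline implements its stated
rules faithfully on well-formed text — it does not bound performance on
real records, where undefined abbreviations and context misreadings are
expected to dominate the error budget, exactly as the confounded corpora
illustrate.

## Numerical and design choices

- Threshold comparisons are strict (`score > 0.5`); with a four-criterion
  denominator the attainable scores are {0, ¼, ⅓, ½, ⅔, ¾, 1}, so no
  floating-point tie-breaking is needed at the default threshold.
- Percentages round half-up to two decimals via `decimal.Decimal`
  (14/19 → 73.68), so printed metric strings are bit-reproducible.
- Tier-2 ontology lookup resolves multi-hits fewest-parents-first, then
  lexicographic code — deterministic and biased toward the more general
  (better-connected) concept.
- The ±40 rectification window is measured around the claimed span
  start; ties resolve to the smallest correction.
- Evidence strings are fixed templates (en dash in ECOG ranges), so
  reports diff cleanly in tests.
- The fixture ontology uses invented NCIt-style codes under the true root
  code C3262; the loader accepts the same TSV dialect for a real
  thesaurus export, and multi-parent concepts are first-class.

## Known limitations

- Negation is sentence-scoped, not scope-directed; a sentence mixing
  affirmed and negated findings over-negates.
- Implicit ECOG inference is a two-bucket heuristic; it cannot produce
  intervals other than [0, 1] and [2, 4].
- Mutation matching is token-level; fusions, exon-level variants and
  pathogenicity qualifiers are out of scope, as are lab-value and
  prior-therapy-line criteria.
- Lesion-site attribution requires the site word in the same sentence as
  the size; cross-sentence anaphora ("the lesion ... It measures 2 cm")
  is not resolved.
- The undefined-abbreviation failure mode is reproduced, not fixed;
  fixing it needs sense disambiguation beyond this rule set.
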