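"""The four criterion extractors and their matching rules."""

import random

import pytest

from trialmatch.criteria import (
    CancerFinding,
    Criterion,
    ECOGRequirement,
    ECOGStatus,
    LesionFinding,
    MutationMention,
    assess_measurability,
    extract_cancer,
    extract_ecog,
    extract_lesions,
    extract_mutations,
    match_cancer,
    match_ecog,
    match_measurable,
    match_mutation,
    protocol_requires_measurable,
)
from trialmatch.documents import DocumentKind, SectionLabel, parse_document
from trialmatch.pipeline import preprocess


def _patient(text):
    return parse_document(text, DocumentKind.PATIENT, "P")


def _protocol(text):
    return parse_document(text, DocumentKind.PROTOCOL, "T")


def _analyze_cancer(doc, resources):
    return extract_cancer(doc, preprocess(doc, resources), resources.index)


# -- cancer type ----------------------------------------------------------


def test_organ_plus_histology_combination(resources):
    doc = _patient("Biopsy of the lung confirmed adenocarcinoma last month.")
    codes = {f.concept_code for f in _analyze_cancer(doc, resources)}
    assert "C3512" in codes  # lung adenocarcinoma via "lung" + "adenocarcinoma"
    assert "C2852" in codes  # the generic first-pass finding remains


def test_full_synonym_phrase_maps_directly(resources):
    doc = _patient("Biopsy confirmed adenocarcinoma of the lung last month.")
    codes = {f.concept_code for f in _analyze_cancer(doc, resources)}
    assert codes == {"C3512"}  # matched whole as an ontology synonym


def test_metastatic_anywhere_in_patient_record(resources):
    doc = _patient(
        "Diagnosed with colon adenocarcinoma. Imaging showed metastatic spread."
    )
    findings = _analyze_cancer(doc, resources)
    assert findings and all(f.metastatic for f in findings)


def test_protocol_metastatic_requires_same_sentence(resources):
    doc = _protocol(
        "Inclusion Criteria:\n- Histologically confirmed colon adenocarcinoma.\n"
        "- Patients with metastatic progression on prior therapy are eligible.\n"
    )
    findings = _analyze_cancer(doc, resources)
    assert findings and not any(f.metastatic for f in findings)


def test_negated_cancer_yields_no_finding(resources):
    doc = _patient("Workup showed no evidence of melanoma.")
    assert _analyze_cancer(doc, resources) == []


def test_undefined_alt_maps_to_tumor_name(resources):
    """The documented failure: an undefined 'ALT' lab abbreviation resolves
    to Atypical Lipomatous Tumor."""
    doc = _protocol(
        "Inclusion Criteria:\n"
        "- Adequate liver function: AST and ALT at most 2.5 times the upper "
        "limit of normal.\n"
    )
    codes = {f.concept_code for f in _analyze_cancer(doc, resources)}
    assert codes == {"C4244"}


def _cf(code, metastatic=False, section=SectionLabel.INCLUSION, source=DocumentKind.PROTOCOL):
    return CancerFinding(
        concept_code=code,
        metastatic=metastatic,
        evidence=code,
        span=(0, 1),
        sentence=0,
        source=source,
        section=section,
    )


def _pf(code, metastatic=False):
    return _cf(code, metastatic, SectionLabel.BODY, DocumentKind.PATIENT)


def test_match_cancer_subtype_with_metastatic_implication(index):
    res = match_cancer([_pf("C3512", True)], [_cf("C2852", True)], index)
    assert res.required_by_protocol and res.satisfied


def test_match_cancer_not_required_when_protocol_silent(index):
    res = match_cancer([_pf("C3512")], [], index)
    assert not res.required_by_protocol and res.satisfied is None


def test_match_cancer_metastatic_requirement_fails_nonmetastatic_patient(index):
    res = match_cancer([_pf("C3512", False)], [_cf("C3512", True)], index)
    assert res.satisfied is False
    assert "does not match" in res.evidence_lines[0]


def test_match_cancer_exclusion_conflict_flagged(index):
    res = match_cancer(
        [_pf("C3512")],
        [_cf("C2852"), _cf("C4878", section=SectionLabel.EXCLUSION)],
        index,
    )
    assert res.satisfied and res.exclusion_conflict
    assert res.exclusion_evidence


def test_match_cancer_monotone_under_protocol_generalization(index):
    """Replacing a required concept by one of its ancestors never turns a
    satisfied match into a non-match."""
    rng = random.Random(9)
    codes = sorted(index.concepts)
    for _ in range(200):
        p = rng.choice(codes)
        q = rng.choice(codes)
        before = match_cancer([_pf(p)], [_cf(q)], index).satisfied
        ancestors = sorted(index.ancestors(q))
        if not ancestors:
            continue
        q2 = rng.choice(ancestors)
        after = match_cancer([_pf(p)], [_cf(q2)], index).satisfied
        if before:
            assert after


# -- performance status ---------------------------------------------------


def test_explicit_protocol_le(resources):
    doc = _protocol("Inclusion Criteria:\n- ECOG performance status ≤ 1.\n")
    req = extract_ecog(doc)
    assert isinstance(req, ECOGRequirement)
    assert req.comparator == "le" and req.bound_high == 1
    assert req.admissible_levels() == {0, 1}


def test_explicit_protocol_range(resources):
    doc = _protocol("Inclusion Criteria:\n- ECOG performance status 0-1.\n")
    req = extract_ecog(doc)
    assert req.comparator == "range" and (req.bound_low, req.bound_high) == (0, 1)


def test_protocol_bare_digit_defaults_to_le():
    doc = _protocol("Inclusion Criteria:\n- ECOG performance status 2.\n")
    req = extract_ecog(doc)
    assert req.comparator == "le" and req.admissible_levels() == {0, 1, 2}


def test_patient_explicit_and_range():
    assert extract_ecog(_patient("ECOG performance status is 2.")) == ECOGStatus(
        2, 2, "explicit", (0, 28)
    )
    status = extract_ecog(_patient("ECOG 0-1 documented."))
    assert (status.min_level, status.max_level) == (0, 1)


def test_patient_implicit_poor_phrase():
    status = extract_ecog(_patient("The patient is wheelchair bound."))
    assert (status.min_level, status.max_level, status.source_kind) == (2, 4, "implicit")


def test_patient_implicit_latest_mention_wins():
    status = extract_ecog(
        _patient("Previously doing well. Now mostly bed bound at home.")
    )
    assert (status.min_level, status.max_level) == (2, 4)


def test_ecog_digit_out_of_range_skipped():
    assert extract_ecog(_patient("ECOG 7 was transcribed in error.")) is None


def test_match_ecog_verbatim_no_match_line():
    res = match_ecog(
        ECOGStatus(2, 2, "explicit", (0, 1)),
        ECOGRequirement("range", 0, 1, (0, 1)),
        patient_id="5",
        protocol_id="3",
    )
    assert res.satisfied is False
    assert res.evidence_lines == [
        "Patient 5 has ECOG status [2] which does not match Protocol 3 "
        "which requires ECOG status of 0–1"
    ]


@pytest.mark.parametrize(
    "status, req, expected",
    [
        (ECOGStatus(0, 1, "implicit", (0, 1)), ECOGRequirement("le", 0, 1, (0, 1)), True),
        (ECOGStatus(0, 1, "implicit", (0, 1)), ECOGRequirement("range", 0, 0, (0, 1)), False),
        (ECOGStatus(2, 4, "implicit", (0, 1)), ECOGRequirement("le", 0, 2, (0, 1)), False),
        (None, ECOGRequirement("le", 0, 1, (0, 1)), False),
    ],
)
def test_match_ecog_conservative_containment(status, req, expected):
    assert match_ecog(status, req).satisfied is expected


def test_match_ecog_not_required_without_requirement():
    res = match_ecog(ECOGStatus(1, 1, "explicit", (0, 1)), None)
    assert not res.required_by_protocol


# -- measurable disease ---------------------------------------------------


@pytest.mark.parametrize(
    "text, category, longest",
    [
        ("CT showed a (2.3 x 1.1) cm lesion in the liver.", "solid_organ", 2.3),
        ("A 1.2 cm axillary lymph node was noted.", "lymph_node", 1.2),
        ("Sclerotic lesion in the L4 vertebra measuring 3.0 cm.", "bone", 3.0),
        ("A (3.0 x 2.1 x 1.4) cm mass in the kidney.", "solid_organ", 3.0),
        ("A 12 mm nodule in the lung.", "solid_organ", 1.2),
    ],
)
def test_extract_lesions_patterns(resources, text, category, longest):
    doc = _patient(text)
    lesions = extract_lesions(doc, preprocess(doc, resources))
    assert len(lesions) == 1
    assert lesions[0].site_category == category
    assert lesions[0].longest_dimension_cm == pytest.approx(longest)


def test_lesion_without_site_is_unknown(resources):
    doc = _patient("A 2.0 cm mass was described elsewhere.")
    lesions = extract_lesions(doc, preprocess(doc, resources))
    assert lesions[0].site_category == "unknown"


def _lesion(category, d):
    return LesionFinding(category, d, (0, 1))


@pytest.mark.parametrize(
    "lesions, expected",
    [
        ([_lesion("bone", 3.0)], False),
        ([_lesion("lymph_node", 1.5)], True),
        ([_lesion("lymph_node", 1.4)], False),
        ([_lesion("solid_organ", 0.8)], False),
        ([_lesion("solid_organ", 1.0)], True),
        ([_lesion("unknown", 5.0)], False),
        ([], False),
    ],
)
def test_assess_measurability_rules(lesions, expected):
    assert assess_measurability(lesions) is expected


def test_measurability_monotone_in_size():
    rng = random.Random(13)
    for _ in range(200):
        lesions = [
            _lesion(rng.choice(["solid_organ", "lymph_node", "bone", "unknown"]),
                    round(rng.uniform(0.1, 3.0), 2))
            for _ in range(rng.randint(1, 4))
        ]
        before = assess_measurability(lesions)
        i = rng.randrange(len(lesions))
        bigger = _lesion(
            lesions[i].site_category, lesions[i].longest_dimension_cm + rng.uniform(0, 2)
        )
        grown = lesions[:i] + [bigger] + lesions[i + 1:]
        if before:
            assert assess_measurability(grown)


@pytest.mark.parametrize(
    "inclusion, expected",
    [
        ("Patients must have measurable disease per RECIST.", True),
        ("Measurable or non-measurable disease allowed.", False),
        ("No relevant phrase at all.", False),
        ("At least one lesion measuring 1 cm or greater.", True),
    ],
)
def test_protocol_requires_measurable(inclusion, expected):
    doc = _protocol(f"Inclusion Criteria:\n- {inclusion}\n")
    assert protocol_requires_measurable(doc) is expected


def test_match_measurable_rules():
    assert match_measurable(True, True).satisfied is True
    assert match_measurable(False, True).satisfied is False
    res = match_measurable(False, False)
    assert not res.required_by_protocol and res.satisfied is None


# -- genetic mutation -----------------------------------------------------


def test_therapy_context_exclusions(resources):
    doc = _patient(
        "Received anti-HER2 therapy and VEGF-targeted therapy. "
        "A pathogenic ATM mutation was found."
    )
    mm = extract_mutations(doc, preprocess(doc, resources))
    by_token = {m.token: m for m in mm}
    assert by_token["HER2"].therapy_context
    assert by_token["VEGF"].therapy_context
    assert not by_token["ATM"].therapy_context


def _mm(token, section=SectionLabel.BODY, therapy=False, negated=False):
    return MutationMention(token, "gene", therapy, negated, section, (0, 1))


def test_mutation_synonym_mismatch_without_table():
    res = match_mutation([_mm("CHEK2")], [_mm("CHK2", SectionLabel.INCLUSION)])
    assert res.required_by_protocol and res.satisfied is False


def test_mutation_expression_variant_mismatch():
    res = match_mutation([_mm("BRCA1 mut")], [_mm("BRCA1", SectionLabel.INCLUSION)])
    assert res.satisfied is False


def test_mutation_overlap_satisfies():
    res = match_mutation(
        [_mm("ATM"), _mm("TP53")],
        [_mm("ATM", SectionLabel.INCLUSION), _mm("ATR", SectionLabel.INCLUSION)],
    )
    assert res.satisfied is True


def test_mutation_synonym_table_resolves_swap():
    synonyms = {"chek2": "chk2"}
    res = match_mutation(
        [_mm("CHEK2")], [_mm("CHK2", SectionLabel.INCLUSION)], synonyms=synonyms
    )
    assert res.satisfied is True


def test_mutation_matching_equals_set_intersection():
    """With synonyms off, the verdict is plain lowercase set intersection."""
    rng = random.Random(31)
    vocab = ["ATM", "ATR", "BRCA1", "BRCA2", "TP53", "KRAS", "CHK2", "PALB2"]
    for _ in range(300):
        pat = rng.sample(vocab, rng.randint(0, 5))
        req = rng.sample(vocab, rng.randint(1, 5))
        res = match_mutation(
            [_mm(t) for t in pat],
            [_mm(t, SectionLabel.INCLUSION) for t in req],
        )
        assert res.satisfied is bool(
            {t.lower() for t in pat} & {t.lower() for t in req}
        )


def test_negated_or_therapy_mentions_never_satisfy():
    res = match_mutation(
        [_mm("ATM", negated=True), _mm("ATR", therapy=True)],
        [_mm("ATM", SectionLabel.INCLUSION), _mm("ATR", SectionLabel.INCLUSION)],
    )
    assert res.satisfied is False


def test_mutation_exclusion_section_is_flag_not_requirement():
    res = match_mutation([_mm("KRAS")], [_mm("KRAS", SectionLabel.EXCLUSION)])
    assert not res.required_by_protocol
    assert res.exclusion_conflict and res.exclusion_evidence
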