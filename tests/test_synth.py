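"""Synthetic corpus generation: rendering, gold labelling, confounders."""

import json

import pytest

from trialmatch.config import RunConfig
from trialmatch.criteria import ECOGRequirement
from trialmatch.documents import parse_document
from trialmatch.pipeline import build_resources, match_pair
from trialmatch.synth import (
    PatientProfile,
    ProtocolProfile,
    generate_corpus,
    gold_label,
    render_patient,
    render_protocol,
)


def _req(comparator="range", low=0, high=1):
    return ECOGRequirement(comparator, low, high, (0, 0))


def test_render_patient_is_deterministic(index):
    profile = PatientProfile("C3512", True, 1, "explicit", mutations=["ATM"])
    t1, a1 = render_patient(profile, 42, index)
    t2, a2 = render_patient(profile, 42, index)
    assert t1 == t2 and a1 == a2


def test_implicit_poor_rendering_has_phrase_but_no_ecog_token(index):
    profile = PatientProfile("C3512", False, 3, "implicit_poor")
    text, _ = render_patient(profile, 1, index)
    assert "ECOG" not in text
    assert any(p in text.lower() for p in ("bed bound", "wheelchair bound", "limited activity"))


def test_gene_synonym_swap_renders_synonym(index):
    profile = PatientProfile(
        "C3512", True, 1, "explicit", mutations=["CHK2"],
        confounders=frozenset({"gene_synonym_swap"}),
    )
    text, ann = render_patient(profile, 2, index)
    assert "CHEK2" in text and "CHK2 " not in text


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        PatientProfile("C3512", False, 3, "implicit_good")
    with pytest.raises(ValueError):
        PatientProfile("C3512", False, 1, "implicit_poor")
    with pytest.raises(ValueError):
        PatientProfile("C3512", False, 1, "explicit", mutations=["ATM"], therapy_mentions=["ATM"])
    with pytest.raises(ValueError):
        ProtocolProfile()  # no criterion at all


def test_render_protocol_contents(index):
    profile = ProtocolProfile(
        required_cancer="C2852",
        requires_metastatic=True,
        ecog_requirement=_req(),
        requires_measurable=False,
        required_mutations=["ATM", "ATR"],
    )
    text, _ = render_protocol(profile, 3, index)
    assert "Inclusion Criteria:" in text and "Exclusion Criteria:" in text
    assert "metastatic adenocarcinoma" in text
    assert "ECOG performance status" in text and "0-1" in text
    assert "ATM" in text and "ATR" in text
    assert "measurable" not in text.lower() and "measuring" not in text.lower()


def test_gold_label_examples(index):
    compatible = PatientProfile(
        "C3512", True, 1, "explicit", lesions=[("solid_organ", (2.0,))], mutations=["ATM"]
    )
    protocol = ProtocolProfile(
        required_cancer="C2852",
        requires_metastatic=True,
        ecog_requirement=_req(),
        requires_measurable=True,
        required_mutations=["ATM", "ATR"],
    )
    assert gold_label(compatible, protocol, index) == "match"
    bad_ecog = PatientProfile(
        "C3512", True, 2, "explicit", lesions=[("solid_organ", (2.0,))], mutations=["ATM"]
    )
    assert gold_label(bad_ecog, protocol, index) == "no_match"


def test_gold_label_uses_true_synonyms_independent_of_pipeline(index):
    """The synonym-swap confounder plants a controlled false negative:
    gold stays a match while the exact-token pipeline misses it."""
    patient = PatientProfile(
        "C3512", True, 1, "explicit", mutations=["CHK2"],
        confounders=frozenset({"gene_synonym_swap"}),
    )
    protocol = ProtocolProfile(required_cancer="C2852", required_mutations=["CHK2"])
    assert gold_label(patient, protocol, index) == "match"
    res = build_resources()
    ptext, _ = render_patient(patient, 4, index)
    qtext, _ = render_protocol(protocol, 4, index)
    report = match_pair(
        parse_document(ptext, "patient", "P"),
        parse_document(qtext, "protocol", "T"),
        res,
    )
    assert report.decision == "no_match"


def test_corpus_enumerates_all_pairs_with_labels():
    bundle = generate_corpus(12, 6, {}, seed=3)
    assert len(bundle.patients) == 12 and len(bundle.protocols) == 6
    assert len(bundle.gold) == 72
    assert set(bundle.gold) == set(bundle.pairs)
    assert set(bundle.gold.values()) <= {"match", "no_match"}


def test_corpus_bundle_roundtrips_to_disk(tmp_path):
    bundle = generate_corpus(3, 2, {}, seed=5, out_dir=tmp_path)
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert len(manifest) == 5
    for entry in manifest:
        assert (tmp_path / entry["path"]).exists()
    gold_lines = (tmp_path / "gold_labels.csv").read_text().strip().splitlines()
    assert len(gold_lines) == 1 + 6  # header + 3x2 pairs
    annotations = json.loads((tmp_path / "annotations.json").read_text())
    assert set(annotations) == {e["id"] for e in manifest}


def test_same_seed_reproduces_identical_bundle():
    b1 = generate_corpus(6, 3, {"size_in_mm": 0.5}, seed=9)
    b2 = generate_corpus(6, 3, {"size_in_mm": 0.5}, seed=9)
    assert [d.text for d in b1.patients + b1.protocols] == [
        d.text for d in b2.patients + b2.protocols
    ]
    assert b1.gold == b2.gold


def test_confounders_change_only_injected_documents():
    """Enabling one confounder type perturbs predictions only on pairs
    whose patient (or protocol) actually received the confounder."""
    res = build_resources()

    def predictions(bundle):
        out = {}
        docs_q = [
            parse_document(q.text, "protocol", q.id) for q in bundle.protocols
        ]
        for p in bundle.patients:
            pdoc = parse_document(p.text, "patient", p.id)
            for q, qdoc in zip(bundle.protocols, docs_q):
                out[(p.id, q.id)] = match_pair(pdoc, qdoc, res).decision
        return out

    clean = generate_corpus(8, 4, {}, seed=21)
    confounded = generate_corpus(8, 4, {"gene_synonym_swap": 1.0}, seed=21)
    # profiles and gold are confounder-independent
    assert clean.gold == confounded.gold
    injected = {
        d.id for d in confounded.patients if d.annotations["applied_confounders"]
    }
    preds_clean = predictions(clean)
    preds_conf = predictions(confounded)
    changed = {pair for pair in preds_clean if preds_clean[pair] != preds_conf[pair]}
    assert all(pid in injected for pid, _ in changed)


def test_gold_is_pipeline_independent(monkeypatch, index):
    """gold_label never calls into extraction/matching code."""
    import trialmatch.criteria as criteria
    import trialmatch.matching as matching

    def _boom(*args, **kwargs):  # pragma: no cover - should never run
        raise AssertionError("gold labelling must not invoke the pipeline")

    for mod, names in [
        (criteria, ["extract_cancer", "match_cancer", "extract_ecog", "match_ecog",
                    "extract_lesions", "match_measurable", "extract_mutations",
                    "match_mutation"]),
        (matching, ["compute_score", "decide", "build_report"]),
    ]:
        for name in names:
            monkeypatch.setattr(mod, name, _boom)
    patient = PatientProfile("C3512", True, 1, "explicit", mutations=["ATM"])
    protocol = ProtocolProfile(required_cancer="C2852", required_mutations=["ATM"])
    assert gold_label(patient, protocol, index) in {"match", "no_match"}


def test_invalid_corpus_arguments_rejected():
    with pytest.raises(ValueError):
        generate_corpus(0, 3, {}, seed=1)
    with pytest.raises(ValueError):
        generate_corpus(3, 3, {"not_a_confounder": 1.0}, seed=1)
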