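"""End-to-end pipeline: preprocessing, extraction, matching for one pair.

The stages mirror the system design: tag entities (built-in lexicon tagger
plus any external tagger outputs supplied through the JSON-lines
contract), rectify and merge by offset, expand abbreviations, flag
negation, run the four criterion extractors, and aggregate the criterion
results into a scored, explained match report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from . import config as cfg
from .config import RunConfig, build_default_lexicon, load_gene_synonyms
from .criteria import (
    CancerFinding,
    ECOGRequirement,
    ECOGStatus,
    MutationMention,
    extract_cancer,
    extract_ecog,
    extract_lesions,
    extract_mutations,
    assess_measurability,
    match_cancer,
    match_ecog,
    match_measurable,
    match_mutation,
    protocol_requires_measurable,
)
from .documents import Document, DocumentKind, parse_document
from .matching import MatchConfig, MatchReport, build_report
from .ontology import OntologyIndex, load_default_index
from .tagging import Lexicon, TaggerOutput, merge_outputs, tag_with_lexicon
from .textprep import NegationConfig, detect_abbreviations, expand_mentions, flag_negation


@dataclass
class Resources:
    """Everything the pipeline needs, bundled once per run."""

    index: OntologyIndex
    lexicon: Lexicon
    negation: NegationConfig
    synonyms: dict[str, str]
    run_config: RunConfig = field(default_factory=RunConfig)

    @property
    def match_config(self) -> MatchConfig:
        return MatchConfig(
            threshold=self.run_config.threshold,
            synonym_table_enabled=self.run_config.synonym_table_enabled,
        )


@lru_cache(maxsize=1)
def _default_index() -> OntologyIndex:
    return load_default_index()


def build_resources(run_config: RunConfig | None = None) -> Resources:
    run_config = run_config or RunConfig()
    if run_config.ontology_path:
        index = OntologyIndex.from_tsv(run_config.ontology_path)
    else:
        index = _default_index()
    if run_config.lexicon_path:
        lexicon = Lexicon.from_tsv(run_config.lexicon_path)
    else:
        lexicon = build_default_lexicon(index)
    if run_config.synonym_table_path:
        synonyms = {}
        from pathlib import Path

        for line in Path(run_config.synonym_table_path).read_text().splitlines():
            if line.strip() and not line.startswith("#"):
                variant, canonical = line.split("\t")[:2]
                synonyms[variant.strip().lower()] = canonical.strip().lower()
    else:
        synonyms = load_gene_synonyms()
    return Resources(
        index=index,
        lexicon=lexicon,
        negation=NegationConfig(list(run_config.negation_triggers)),
        synonyms=synonyms,
        run_config=run_config,
    )


def preprocess(
    doc: Document,
    resources: Resources,
    external_outputs: tuple[TaggerOutput, ...] = (),
):
    """Tag, rectify+merge, expand abbreviations, flag negation."""
    outputs = [tag_with_lexicon(doc, resources.lexicon), *external_outputs]
    merged = merge_outputs(
        outputs, doc.raw_text, window=resources.run_config.rectify_window
    )
    abbrev = detect_abbreviations(doc)
    merged = expand_mentions(merged, abbrev)
    return flag_negation(doc, merged, resources.negation)


@dataclass
class PatientAnalysis:
    doc: Document
    cancer_findings: list[CancerFinding]
    ecog: ECOGStatus | None
    lesions: list
    measurable: bool
    mutations: list[MutationMention]


@dataclass
class ProtocolAnalysis:
    doc: Document
    cancer_findings: list[CancerFinding]
    ecog: ECOGRequirement | None
    requires_measurable: bool
    mutations: list[MutationMention]


def analyze_patient(
    doc: Document,
    resources: Resources,
    external_outputs: tuple[TaggerOutput, ...] = (),
) -> PatientAnalysis:
    rc = resources.run_config
    mentions = preprocess(doc, resources, external_outputs)
    lesions = extract_lesions(doc, mentions, rc.site_map)
    return PatientAnalysis(
        doc=doc,
        cancer_findings=extract_cancer(doc, mentions, resources.index),
        ecog=extract_ecog(doc, rc.good_health_phrases, rc.poor_health_phrases),
        lesions=lesions,
        measurable=assess_measurability(lesions, inclusive=rc.measurability_inclusive),
        mutations=extract_mutations(doc, mentions),
    )


def analyze_protocol(
    doc: Document,
    resources: Resources,
    external_outputs: tuple[TaggerOutput, ...] = (),
) -> ProtocolAnalysis:
    mentions = preprocess(doc, resources, external_outputs)
    return ProtocolAnalysis(
        doc=doc,
        cancer_findings=extract_cancer(doc, mentions, resources.index),
        ecog=extract_ecog(doc),
        requires_measurable=protocol_requires_measurable(doc),
        mutations=extract_mutations(doc, mentions),
    )


def match_pair(
    patient_doc: Document,
    protocol_doc: Document,
    resources: Resources | None = None,
) -> MatchReport:
    """Run the full pipeline on one patient-protocol pair."""
    resources = resources or build_resources()
    pa = analyze_patient(patient_doc, resources)
    qa = analyze_protocol(protocol_doc, resources)
    pid, qid = patient_doc.id, protocol_doc.id
    synonyms = (
        resources.synonyms if resources.run_config.synonym_table_enabled else None
    )
    results = [
        match_cancer(pa.cancer_findings, qa.cancer_findings, resources.index, pid, qid),
        match_ecog(pa.ecog, qa.ecog, pid, qid),
        match_measurable(pa.measurable, qa.requires_measurable, pid, qid),
        match_mutation(pa.mutations, qa.mutations, synonyms, pid, qid),
    ]
    return build_report(patient_doc, protocol_doc, results, resources.match_config)


def match_texts(
    patient_text: str,
    protocol_text: str,
    resources: Resources | None = None,
    patient_id: str = "patient",
    protocol_id: str = "protocol",
) -> MatchReport:
    """Convenience wrapper over raw strings."""
    patient_doc = parse_document(patient_text, DocumentKind.PATIENT, patient_id)
    protocol_doc = parse_document(protocol_text, DocumentKind.PROTOCOL, protocol_id)
    return match_pair(patient_doc, protocol_doc, resources)
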