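"""The four eligibility criteria: extraction and per-criterion matching.

Each criterion follows the same shape: extract structured findings from a
patient record and from a protocol, then compare them into a
:class:`CriterionResult` that records whether the protocol requires the
criterion at all, whether the patient satisfies it, and human-readable
evidence naming both sides.  A criterion counts as *required* exactly when
the protocol's inclusion section yields at least one non-negated finding
for it — that is what puts it in the matching-score denominator.

Cancer type matches through the ontology: the patient's concept must be a
subtype of a protocol concept, and if the protocol's concept is metastatic
the patient must be too.  ECOG matching is conservative interval
containment.  Measurable disease follows RECIST 1.1: a solid-organ lesion
of at least 1 cm or a lymph node of at least 1.5 cm qualifies; bone never
does.  Mutations match on exact token overlap, optionally canonicalised
through a gene-synonym table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

from . import config as cfg
from .documents import Document, DocumentKind, SectionLabel, Span, section_of
from .ontology import OntologyIndex, is_subtype, map_to_concept
from .tagging import EntityMention

log = logging.getLogger(__name__)


class Criterion(str, Enum):
    CANCER_TYPE = "cancer_type"
    ECOG = "ecog"
    MEASURABLE = "measurable"
    MUTATION = "mutation"


CRITERION_ORDER = [
    Criterion.CANCER_TYPE,
    Criterion.ECOG,
    Criterion.MEASURABLE,
    Criterion.MUTATION,
]


# -- domain types ---------------------------------------------------------


@dataclass(frozen=True)
class CancerFinding:
    concept_code: str
    metastatic: bool
    evidence: str  # surface or combined organ+histology string
    span: Span
    sentence: int
    source: DocumentKind
    section: SectionLabel


@dataclass(frozen=True)
class ECOGStatus:
    min_level: int
    max_level: int
    source_kind: str  # "explicit" | "implicit"
    evidence: Span

    def __post_init__(self) -> None:
        if not 0 <= self.min_level <= self.max_level <= 4:
            raise ValueError("ECOG levels must satisfy 0 <= min <= max <= 4")


@dataclass(frozen=True)
class ECOGRequirement:
    comparator: str  # "le" | "ge" | "range" | "eq"
    bound_low: int
    bound_high: int
    evidence: Span

    def __post_init__(self) -> None:
        if not (0 <= self.bound_low <= 4 and 0 <= self.bound_high <= 4):
            raise ValueError("ECOG bounds must lie in 0-4")
        if self.comparator == "range" and self.bound_low > self.bound_high:
            raise ValueError("range requires bound_low <= bound_high")

    def admissible_levels(self) -> set[int]:
        if self.comparator == "le":
            return set(range(0, self.bound_high + 1))
        if self.comparator == "ge":
            return set(range(self.bound_low, 5))
        if self.comparator == "eq":
            return {self.bound_high}
        return set(range(self.bound_low, self.bound_high + 1))

    def render(self) -> str:
        levels = sorted(self.admissible_levels())
        if len(levels) == 1:
            return str(levels[0])
        return f"{levels[0]}–{levels[-1]}"  # en dash, as printed in reports


@dataclass(frozen=True)
class LesionFinding:
    site_category: str  # "solid_organ" | "lymph_node" | "bone" | "unknown"
    longest_dimension_cm: float | None
    evidence: Span
    site_word: str | None = None


@dataclass(frozen=True)
class MutationMention:
    token: str
    tag: str
    therapy_context: bool
    negated: bool
    section: SectionLabel
    span: Span


@dataclass
class CriterionResult:
    criterion: Criterion
    required_by_protocol: bool
    satisfied: bool | None
    evidence_lines: list[str] = field(default_factory=list)
    exclusion_conflict: bool = False
    exclusion_evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.required_by_protocol:
            self.satisfied = None
        elif self.satisfied is None:
            raise ValueError("required criterion must carry a satisfied verdict")
        if self.required_by_protocol and not self.evidence_lines:
            raise ValueError("required criterion must carry evidence lines")


# -- cancer type ----------------------------------------------------------

_METASTATIC_RE = re.compile(r"\bmetastat\w*", re.IGNORECASE)


def extract_cancer(
    doc: Document,
    mentions: list[EntityMention],
    index: OntologyIndex,
    disease_tags: set[str] | None = None,
) -> list[CancerFinding]:
    """Map disease mentions to ontology concepts and resolve metastatic status.

    First pass maps each non-negated disease-tagged mention through the
    two-tier lookup.  Second pass combines organ mentions with a cancer
    finding in the same sentence ("lung" + "adenocarcinoma" -> "lung
    adenocarcinoma") and keeps the more specific concept when it resolves.
    Metastatic status: for a patient, a metastasis cue anywhere in the
    record marks every finding metastatic; for a protocol, cue and cancer
    must share a sentence.
    """
    disease_tags = disease_tags or cfg.DISEASE_TAGS
    text = doc.raw_text

    primary: list[tuple[EntityMention, str]] = []
    for m in mentions:
        if m.negated or not (m.tag_labels() & disease_tags):
            continue
        code = map_to_concept(m.matching_surface, index)
        if code is not None:
            primary.append((m, code))

    combined: list[tuple[EntityMention, str, str]] = []
    organ_mentions = [m for m in mentions if "organ" in m.tag_labels() and not m.negated]
    for organ in organ_mentions:
        o_sent = doc.sentence_index(organ.start)
        for cm, code in primary:
            if doc.sentence_index(cm.start) != o_sent:
                continue
            term = f"{organ.surface} {cm.matching_surface}"
            c2 = map_to_concept(term, index)
            if c2 is not None and c2 != code:
                combined.append((cm, c2, term))

    met_cue_sentences = {
        doc.sentence_index(m.start)
        for m in mentions
        if not m.negated
        and ({"Metastasis", "Secondary_Malignant"} & m.tag_labels()
             or _METASTATIC_RE.fullmatch(m.surface))
    }
    for m in _METASTATIC_RE.finditer(text):
        met_cue_sentences.add(doc.sentence_index(m.start()))
    patient_metastatic = doc.kind is DocumentKind.PATIENT and bool(met_cue_sentences)

    findings: list[CancerFinding] = []
    seen: set[tuple[str, int, SectionLabel, bool]] = set()

    def _add(mention: EntityMention, code: str, evidence: str) -> None:
        sent = doc.sentence_index(mention.start)
        if doc.kind is DocumentKind.PATIENT:
            metastatic = patient_metastatic
        else:
            metastatic = sent in met_cue_sentences
        key = (code, sent, section_of(doc, mention.start), metastatic)
        if key in seen:
            return
        seen.add(key)
        findings.append(
            CancerFinding(
                concept_code=code,
                metastatic=metastatic,
                evidence=evidence,
                span=mention.span,
                sentence=sent,
                source=doc.kind,
                section=key[2],
            )
        )

    for m, code in primary:
        _add(m, code, m.matching_surface)
    for m, code, term in combined:
        _add(m, code, term)
    return findings


def match_cancer(
    patient: list[CancerFinding],
    protocol: list[CancerFinding],
    index: OntologyIndex,
    patient_id: str = "patient",
    protocol_id: str = "protocol",
) -> CriterionResult:
    """Subtype-aware cancer-type matching with metastatic implication.

    Required iff the protocol's inclusion section produced a finding.
    Satisfied iff some patient concept is a subtype of some required
    concept and, when the requirement is metastatic, the patient is too.
    A patient concept falling under an exclusion-section concept raises an
    exclusion conflict (flagged, never scored).
    """
    required_findings = [f for f in protocol if f.section is SectionLabel.INCLUSION]
    excluded_findings = [f for f in protocol if f.section is SectionLabel.EXCLUSION]
    required = bool(required_findings)

    def _name(f: CancerFinding) -> str:
        name = index.name_of(f.concept_code)
        return f"metastatic {name}" if f.metastatic else name

    conflict_pairs = [
        (p, q)
        for p in patient
        for q in excluded_findings
        if is_subtype(p.concept_code, q.concept_code, index)
    ]
    exclusion_evidence = [
        f"Patient {patient_id} cancer type {index.name_of(p.concept_code)} falls under "
        f"Protocol {protocol_id} exclusion {index.name_of(q.concept_code)}"
        for p, q in conflict_pairs
    ]

    if not required:
        return CriterionResult(
            criterion=Criterion.CANCER_TYPE,
            required_by_protocol=False,
            satisfied=None,
            exclusion_conflict=bool(conflict_pairs),
            exclusion_evidence=exclusion_evidence,
        )

    matched = next(
        (
            (p, q)
            for p in patient
            for q in required_findings
            if is_subtype(p.concept_code, q.concept_code, index)
            and (not q.metastatic or p.metastatic)
        ),
        None,
    )
    req_names = sorted({_name(q) for q in required_findings})
    if matched:
        p, q = matched
        line = (
            f"Patient {patient_id} has cancer type {_name(p)} which matches "
            f"Protocol {protocol_id} which requires cancer type {_name(q)}"
        )
    else:
        pat_names = sorted({_name(p) for p in patient}) or ["none detected"]
        line = (
            f"Patient {patient_id} has cancer type [{', '.join(pat_names)}] "
            f"which does not match Protocol {protocol_id} which requires "
            f"cancer type [{', '.join(req_names)}]"
        )
    return CriterionResult(
        criterion=Criterion.CANCER_TYPE,
        required_by_protocol=True,
        satisfied=matched is not None,
        evidence_lines=[line],
        exclusion_conflict=bool(conflict_pairs),
        exclusion_evidence=exclusion_evidence,
    )


# -- performance status ---------------------------------------------------

_ECOG_RE = re.compile(
    r"ECOG(?P<mid>[^0-9\n.]{0,40}?)(?P<cmp><=|>=|[≤≥=])?\s*"
    r"(?P<a>\d)(?:\s*[-–—]\s*(?P<b>\d))?"
)


def extract_ecog(
    doc: Document,
    good_phrases: list[str] | None = None,
    poor_phrases: list[str] | None = None,
) -> ECOGStatus | ECOGRequirement | None:
    """Explicit regex extraction around the "ECOG" keyword, with an
    implicit phrase-lexicon fallback for patient records.

    Protocols yield an :class:`ECOGRequirement` (comparator defaults to
    ``le`` when absent); patients yield an :class:`ECOGStatus`.  When both
    good- and poor-health phrases occur, the mention latest in the record
    wins.
    """
    text = doc.raw_text
    for m in _ECOG_RE.finditer(text):
        a = int(m.group("a"))
        b = int(m.group("b")) if m.group("b") else None
        if a > 4 or (b is not None and b > 4):
            log.warning("ECOG value outside 0-4 near offset %d; skipped", m.start())
            continue
        span = (m.start(), m.end())
        if doc.kind is DocumentKind.PROTOCOL:
            comparator = m.group("cmp")
            if b is not None:
                lo, hi = min(a, b), max(a, b)
                return ECOGRequirement("range", lo, hi, span)
            if comparator in (">=", "≥"):
                return ECOGRequirement("ge", a, a, span)
            if comparator == "=":
                return ECOGRequirement("eq", a, a, span)
            return ECOGRequirement("le", 0, a, span)  # default reading
        lo, hi = (a, b) if b is not None else (a, a)
        if lo > hi:
            lo, hi = hi, lo
        return ECOGStatus(lo, hi, "explicit", span)

    if doc.kind is DocumentKind.PROTOCOL:
        return None

    good_phrases = good_phrases or cfg.GOOD_HEALTH_PHRASES
    poor_phrases = poor_phrases or cfg.POOR_HEALTH_PHRASES
    best: tuple[int, str, Span] | None = None
    for phrase, kind in [(p, "good") for p in good_phrases] + [
        (p, "poor") for p in poor_phrases
    ]:
        for m in re.finditer(rf"\b{re.escape(phrase)}\b", text, re.IGNORECASE):
            if best is None or m.start() > best[0]:
                best = (m.start(), kind, (m.start(), m.end()))
    if best is None:
        return None
    _, kind, span = best
    return (
        ECOGStatus(0, 1, "implicit", span)
        if kind == "good"
        else ECOGStatus(2, 4, "implicit", span)
    )


def match_ecog(
    status: ECOGStatus | None,
    req: ECOGRequirement | None,
    patient_id: str = "patient",
    protocol_id: str = "protocol",
) -> CriterionResult:
    """Conservative containment: the whole patient interval must fit the
    requirement's admissible levels."""
    if req is None:
        return CriterionResult(Criterion.ECOG, False, None)
    req_str = req.render()
    if status is None:
        line = (
            f"Patient {patient_id} has no documented ECOG status which does not "
            f"match Protocol {protocol_id} which requires ECOG status of {req_str}"
        )
        return CriterionResult(Criterion.ECOG, True, False, [line])
    admissible = req.admissible_levels()
    satisfied = set(range(status.min_level, status.max_level + 1)) <= admissible
    if status.min_level == status.max_level:
        status_str = f"[{status.min_level}]"
    else:
        status_str = f"[{status.min_level}-{status.max_level}]"
    verb = "matches" if satisfied else "does not match"
    line = (
        f"Patient {patient_id} has ECOG status {status_str} which {verb} "
        f"Protocol {protocol_id} which requires ECOG status of {req_str}"
    )
    if status.source_kind == "implicit":
        line += " (patient status inferred from narrative phrases)"
    return CriterionResult(Criterion.ECOG, True, satisfied, [line])


# -- measurable disease ---------------------------------------------------

_NUM = r"\d+(?:\.\d+)?"
_SIZE_RE = re.compile(
    rf"\(?\s*(?P<a>{_NUM})(?:\s*[x×]\s*(?P<b>{_NUM}))?"
    rf"(?:\s*[x×]\s*(?P<c>{_NUM}))?\s*\)?\s*(?P<unit>cm|mm)\b",
    re.IGNORECASE,
)


def extract_lesions(
    doc: Document,
    mentions: list[EntityMention],
    site_map: dict[str, str] | None = None,
) -> list[LesionFinding]:
    """Parse lesion sizes and attach each to a site in the same sentence.

    Recognised size renderings: ``(a x b) cm``, ``(a x b x c) cm``,
    ``a.b cm`` and bare ``a cm`` (also mm, converted to cm).  Only the
    longest dimension is kept.  A size with no site keyword in its
    sentence is categorised ``unknown``.
    """
    site_map = site_map or cfg.DEFAULT_SITE_MAP
    site_keys = sorted(site_map, key=len, reverse=True)
    text = doc.raw_text
    findings: list[LesionFinding] = []
    for s, e in doc.sentences:
        sent = text[s:e]
        sent_low = sent.lower()
        site_word = None
        for key in site_keys:
            if re.search(rf"(?<![a-z]){re.escape(key)}(?![a-z])", sent_low):
                site_word = key
                break
        for m in _SIZE_RE.finditer(sent):
            dims = []
            for g in ("a", "b", "c"):
                if m.group(g) is not None:
                    try:
                        dims.append(float(m.group(g)))
                    except ValueError:  # pragma: no cover - regex guarantees floats
                        log.warning("malformed lesion size %r skipped", m.group(g))
            if not dims:
                continue
            longest = max(dims)
            if m.group("unit").lower() == "mm":
                longest /= 10.0
            findings.append(
                LesionFinding(
                    site_category=site_map[site_word] if site_word else "unknown",
                    longest_dimension_cm=longest,
                    evidence=(s + m.start(), s + m.end()),
                    site_word=site_word,
                )
            )
    return findings


def assess_measurability(
    lesions: list[LesionFinding],
    solid_min_cm: float = 1.0,
    node_min_cm: float = 1.5,
    inclusive: bool = True,
) -> bool:
    """RECIST 1.1 rule: solid-organ lesion >= 1 cm or lymph node >= 1.5 cm.

    Bone and unknown-site lesions never qualify.  ``inclusive`` switches
    the comparator between >= (default) and strict >.
    """
    def ok(d: float, lim: float) -> bool:
        return d >= lim if inclusive else d > lim

    for lesion in lesions:
        d = lesion.longest_dimension_cm
        if d is None:
            continue
        if lesion.site_category == "solid_organ" and ok(d, solid_min_cm):
            return True
        if lesion.site_category == "lymph_node" and ok(d, node_min_cm):
            return True
    return False


def protocol_requires_measurable(doc: Document) -> bool:
    """True iff the inclusion section asks for measurable disease.

    The phrase cues are "measurable disease" or "measuring"; any mention
    of "non-measurable disease" withdraws the requirement.
    """
    text = doc.section_text(SectionLabel.INCLUSION).lower()
    if not text:
        return False
    if "non-measurable disease" in text or "non measurable disease" in text:
        return False
    return "measurable disease" in text or "measuring" in text


def match_measurable(
    patient_measurable: bool,
    required: bool,
    patient_id: str = "patient",
    protocol_id: str = "protocol",
) -> CriterionResult:
    """When not required, every patient qualifies and the criterion stays
    out of the score denominator."""
    if not required:
        return CriterionResult(Criterion.MEASURABLE, False, None)
    if patient_measurable:
        line = (
            f"Patient {patient_id} has measurable disease which matches "
            f"Protocol {protocol_id} which requires measurable disease"
        )
    else:
        line = (
            f"Patient {patient_id} does not have measurable disease which does "
            f"not match Protocol {protocol_id} which requires measurable disease"
        )
    return CriterionResult(Criterion.MEASURABLE, True, patient_measurable, [line])


# -- genetic mutation -----------------------------------------------------

_ANTI_RE = re.compile(r"anti[\s-]$", re.IGNORECASE)
_TARGETED_RE = re.compile(r"^[\s-]targeted\b", re.IGNORECASE)


def extract_mutations(
    doc: Document,
    mentions: list[EntityMention],
    mutation_tags: set[str] | None = None,
) -> list[MutationMention]:
    """Collect gene/mutation/DNA-tagged tokens, marking therapy contexts.

    A token immediately preceded by "anti-"/"anti " or immediately
    followed by "-targeted"/" targeted" names a therapy, not a patient
    mutation, and is excluded from matching.
    """
    mutation_tags = mutation_tags or cfg.MUTATION_TAGS
    text = doc.raw_text
    out: list[MutationMention] = []
    for m in mentions:
        if not (m.tag_labels() & mutation_tags):
            continue
        therapy = bool(
            _ANTI_RE.search(text, 0, m.start) or _TARGETED_RE.match(text[m.end:])
        )
        out.append(
            MutationMention(
                token=m.matching_surface,
                tag=next(t for t, _ in m.tags if t in mutation_tags),
                therapy_context=therapy,
                negated=m.negated,
                section=section_of(doc, m.start),
                span=m.span,
            )
        )
    return out


def match_mutation(
    patient: list[MutationMention],
    protocol: list[MutationMention],
    synonyms: dict[str, str] | None = None,
    patient_id: str = "patient",
    protocol_id: str = "protocol",
) -> CriterionResult:
    """Token-overlap matching, case-insensitive, exact strings.

    With a synonym table supplied, tokens are canonicalised before
    intersecting (so CHEK2 meets CHK2); without one, expression variants
    like "BRCA1 mut" fail to meet "BRCA1" — the documented behaviour of
    exact-token systems.
    """
    def canon(token: str) -> str:
        t = token.strip().lower()
        return synonyms.get(t, t) if synonyms else t

    def eligible(mm: MutationMention) -> bool:
        return not mm.therapy_context and not mm.negated

    required_tokens = {
        canon(mm.token): mm.token
        for mm in protocol
        if eligible(mm) and mm.section is SectionLabel.INCLUSION
    }
    excluded_tokens = {
        canon(mm.token): mm.token
        for mm in protocol
        if eligible(mm) and mm.section is SectionLabel.EXCLUSION
    }
    patient_tokens = {canon(mm.token): mm.token for mm in patient if eligible(mm)}

    conflict = sorted(set(excluded_tokens) & set(patient_tokens))
    exclusion_evidence = [
        f"Patient {patient_id} mutation {patient_tokens[t]} appears in "
        f"Protocol {protocol_id} exclusion criteria"
        for t in conflict
    ]

    if not required_tokens:
        return CriterionResult(
            Criterion.MUTATION,
            False,
            None,
            exclusion_conflict=bool(conflict),
            exclusion_evidence=exclusion_evidence,
        )

    overlap = sorted(set(required_tokens) & set(patient_tokens))
    req_disp = ", ".join(sorted(required_tokens.values()))
    if overlap:
        got = ", ".join(patient_tokens[t] for t in overlap)
        line = (
            f"Patient {patient_id} has genetic mutation [{got}] which matches "
            f"Protocol {protocol_id} which requires a mutation in [{req_disp}]"
        )
    else:
        pat_disp = ", ".join(sorted(patient_tokens.values())) or "none detected"
        line = (
            f"Patient {patient_id} has genetic mutations [{pat_disp}] which does "
            f"not match Protocol {protocol_id} which requires a mutation in "
            f"[{req_disp}]"
        )
    return CriterionResult(
        Criterion.MUTATION,
        True,
        bool(overlap),
        [line],
        exclusion_conflict=bool(conflict),
        exclusion_evidence=exclusion_evidence,
    )
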