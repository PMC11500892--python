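"""Synthetic patient records, protocols and gold labels.

No public corpus of phase 1 oncology patient records and protocols exists,
so this module generates one: template-based narrative patient notes
(cancer and organ mentions, explicit or implicit ECOG phrasing, lesion
sizes in the renderings clinical notes actually use, mutation lists,
therapy confounders) and protocols with Inclusion/Exclusion sections.
Everything is seeded and byte-reproducible; variability comes from seeded
template choice, not from a language model.

Gold labelling is pipeline-independent by construction: the label is
computed directly from the profile logic (subtype via the fixture
ontology's parent edges, metastatic implication, ECOG interval
containment, RECIST thresholds, mutation intersection with true synonym
resolution) without ever touching the extraction or matching code.  A
pair is gold *match* iff every requirement the protocol states is
satisfied.

Controlled confounders reproduce the error modes rule-based matchers are
known for: an undefined clinical abbreviation that collides with a tumor
name (ALT), a negated cancer distractor, a gene synonym swap (CHEK2 for
CHK2), an expression variant ("BRCA1 mut"), and millimetre lesion sizes.
Confounders change only the rendering — profiles and gold labels are
untouched — so every divergence between gold and pipeline output is a
planted, attributable error.

Patients are rejection-sampled so that each of the ``n_patients x
n_protocols`` pairs is *decisive*: the patient either satisfies every
stated requirement or at most half of them.  This keeps the all-criteria
gold rule and the strict >0.5 score threshold in agreement on a clean
corpus, which is what makes end-to-end recovery a meaningful check of the
extraction pipeline rather than of the threshold rule.
"""

from __future__ import annotations

import csv
import json
import random
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .criteria import ECOGRequirement
from .ontology import OntologyIndex, load_default_index

CONFOUNDERS = frozenset(
    {
        "undefined_abbrev",
        "negated_cancer",
        "gene_synonym_swap",
        "expression_variant",
        "size_in_mm",
    }
)

#: true gene synonym pairs used for gold labelling and for rendering swaps
_SWAP_RENDER = {"CHK2": "CHEK2", "HER2": "ERBB2"}
_TRUE_SYNONYMS = {"chek2": "chk2", "erbb2": "her2"}

#: specific, renderable cancer concepts patients can carry
PATIENT_CANCERS = [
    "C3512",  # Lung Adenocarcinoma
    "C4349",  # Colon Adenocarcinoma
    "C8294",  # Pancreatic Adenocarcinoma
    "C4004",  # Gastric Adenocarcinoma
    "C4872",  # Breast Carcinoma
    "C9131",  # Triple-Negative Breast Carcinoma
    "C2919",  # Prostate Adenocarcinoma
    "C7700",  # Ovarian Serous Adenocarcinoma
    "C3099",  # Hepatocellular Carcinoma
    "C9385",  # Renal Cell Carcinoma
    "C4030",  # Urothelial Carcinoma
    "C6010",  # Head and Neck Squamous Cell Carcinoma
    "C3802",  # Cutaneous Melanoma
    "C9145",  # Osteosarcoma
    "C3158",  # Leiomyosarcoma
    "C8851",  # Diffuse Large B-Cell Lymphoma
    "C3058",  # Glioblastoma
    "C2853",  # Mucinous Adenocarcinoma
]

#: concepts protocols may require (mix of broad and specific)
PROTOCOL_CANCERS = [
    "C2852",  # Adenocarcinoma
    "C2916",  # Carcinoma
    "C9118",  # Sarcoma
    "C3224",  # Melanoma
    "C3208",  # Lymphoma
    "C2929",  # Squamous Cell Carcinoma
    "C4872",  # Breast Carcinoma
    "C3512",  # Lung Adenocarcinoma
    "C5105",  # Colorectal Carcinoma
    "C4908",  # Ovarian Carcinoma
]

#: cancer concepts renderable as "<histology> of the <organ>" where the
#: combined "<organ> <histology>" string resolves in the fixture ontology
COMBINABLE = {
    "C3512": ("lung", "adenocarcinoma"),
    "C4349": ("colon", "adenocarcinoma"),
    "C8294": ("pancreas", "adenocarcinoma"),
    "C4004": ("stomach", "adenocarcinoma"),
}

MUTATION_POOL = [
    "ATM", "ATR", "BRCA1", "BRCA2", "PALB2", "CHK2", "TP53", "ARID1A",
    "RAD54L", "KRAS", "PIK3CA", "MLH1", "BRIP1", "CDK12",
]
THERAPY_GENES = ["HER2", "VEGF", "EGFR"]

_SOLID_SITES = ["liver", "lung", "kidney", "spleen"]
_NODE_SITES = ["axillary lymph node", "cervical lymph node", "mediastinal lymph node"]
_BONE_SITES = ["L4 vertebra", "right femur", "iliac bone"]

_GENERIC_EXCLUSIONS = [
    "Uncontrolled intercurrent illness.",
    "Pregnancy or breastfeeding.",
    "Major surgery within 4 weeks of enrollment.",
    "Known hypersensitivity to the study drug.",
    "Inability to swallow oral medication.",
]

_LIVER_FUNCTION_LINE = (
    "Adequate liver function: AST and ALT at most 2.5 times the upper limit "
    "of normal; albumin at least 2.5 g/dL."
)


@dataclass
class PatientProfile:
    cancer_concept: str
    metastatic: bool
    ecog: int
    ecog_rendering: str  # explicit | implicit_good | implicit_poor | absent
    lesions: list[tuple[str, tuple[float, ...]]] = field(default_factory=list)
    mutations: list[str] = field(default_factory=list)
    therapy_mentions: list[str] = field(default_factory=list)
    confounders: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.ecog <= 4:
            raise ValueError("ecog must lie in 0-4")
        if self.ecog_rendering == "implicit_good" and self.ecog > 1:
            raise ValueError("implicit_good requires ecog <= 1")
        if self.ecog_rendering == "implicit_poor" and self.ecog < 2:
            raise ValueError("implicit_poor requires ecog >= 2")
        if set(self.mutations) & set(self.therapy_mentions):
            raise ValueError("therapy mentions must be disjoint from mutations")
        unknown = set(self.confounders) - CONFOUNDERS
        if unknown:
            raise ValueError(f"unknown confounders: {sorted(unknown)}")


@dataclass
class ProtocolProfile:
    required_cancer: str | None = None
    requires_metastatic: bool = False
    ecog_requirement: ECOGRequirement | None = None
    requires_measurable: bool = False
    required_mutations: list[str] = field(default_factory=list)
    exclusion_items: list[str] = field(default_factory=list)
    confounders: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (
            self.required_cancer
            or self.ecog_requirement
            or self.requires_measurable
            or self.required_mutations
        ):
            raise ValueError("protocol must state at least one criterion")


# -- gold labelling (no pipeline code involved) ---------------------------


def _is_descendant(index: OntologyIndex, child: str, ancestor: str) -> bool:
    if child == ancestor:
        return True
    frontier = list(index.concepts[child].parents)
    seen = set()
    while frontier:
        cur = frontier.pop()
        if cur == ancestor:
            return True
        if cur in seen:
            continue
        seen.add(cur)
        frontier.extend(index.concepts[cur].parents)
    return False


def _canon_gene(token: str) -> str:
    t = token.strip().lower()
    return _TRUE_SYNONYMS.get(t, t)


def _ecog_interval(profile: PatientProfile) -> tuple[int, int] | None:
    if profile.ecog_rendering == "explicit":
        return (profile.ecog, profile.ecog)
    if profile.ecog_rendering == "implicit_good":
        return (0, 1)
    if profile.ecog_rendering == "implicit_poor":
        return (2, 4)
    return None


def _patient_measurable(profile: PatientProfile) -> bool:
    for category, dims in profile.lesions:
        longest = max(dims)
        if category == "solid_organ" and longest >= 1.0:
            return True
        if category == "lymph_node" and longest >= 1.5:
            return True
    return False


def criterion_verdicts(
    patient: PatientProfile,
    protocol: ProtocolProfile,
    index: OntologyIndex,
) -> dict[str, bool]:
    """Per-criterion gold verdicts, for the criteria the protocol states."""
    verdicts: dict[str, bool] = {}
    if protocol.required_cancer:
        verdicts["cancer_type"] = _is_descendant(
            index, patient.cancer_concept, protocol.required_cancer
        ) and (not protocol.requires_metastatic or patient.metastatic)
    if protocol.ecog_requirement:
        interval = _ecog_interval(patient)
        if interval is None:
            verdicts["ecog"] = False
        else:
            admissible = protocol.ecog_requirement.admissible_levels()
            verdicts["ecog"] = set(range(interval[0], interval[1] + 1)) <= admissible
    if protocol.requires_measurable:
        verdicts["measurable"] = _patient_measurable(patient)
    if protocol.required_mutations:
        req = {_canon_gene(g) for g in protocol.required_mutations}
        got = {_canon_gene(g) for g in patient.mutations}
        verdicts["mutation"] = bool(req & got)
    return verdicts


def gold_label(
    patient: PatientProfile,
    protocol: ProtocolProfile,
    index: OntologyIndex | None = None,
) -> str:
    """Physician-style gold: match iff every stated requirement is met."""
    index = index or load_default_index()
    verdicts = criterion_verdicts(patient, protocol, index)
    return "match" if all(verdicts.values()) else "no_match"


def _is_decisive(
    patient: PatientProfile, protocol: ProtocolProfile, index: OntologyIndex
) -> bool:
    verdicts = criterion_verdicts(patient, protocol, index)
    n = len(verdicts)
    k = sum(verdicts.values())
    return not (n / 2 < k < n)


# -- rendering ------------------------------------------------------------


def _fmt_cm(value: float) -> str:
    return f"{value:.1f}"


def _render_size(dims: tuple[float, ...], in_mm: bool, rng: random.Random) -> str:
    if in_mm:
        mm = [str(int(round(d * 10))) for d in dims]
        if len(mm) == 1:
            return f"{mm[0]} mm"
        return "(" + " x ".join(mm) + ") mm"
    cm = [_fmt_cm(d) for d in dims]
    if len(cm) == 1:
        return rng.choice([f"{cm[0]} cm", f"({cm[0]}) cm"])
    return "(" + " x ".join(cm) + ") cm"


def _join_tokens(tokens: list[str]) -> str:
    if len(tokens) == 1:
        return tokens[0]
    return ", ".join(tokens[:-1]) + " and " + tokens[-1]


def render_patient(
    profile: PatientProfile, seed: int, index: OntologyIndex | None = None
) -> tuple[str, dict]:
    """Deterministic narrative note for one patient profile.

    Returns the text and a gold-annotation dict recording every planted
    item with its character span.
    """
    index = index or load_default_index()
    rng = random.Random(f"patient-render:{seed}")
    sentences: list[str] = []
    plants: list[tuple[str, str, str]] = []  # (kind, value, planted substring)

    age = rng.randint(41, 79)
    sex = rng.choice(["man", "woman"])
    name = index.name_of(profile.cancer_concept).lower()
    met = "metastatic " if profile.metastatic else ""
    variant = rng.random()
    if profile.cancer_concept in COMBINABLE and variant < 0.25:
        # full prepositional synonym ("adenocarcinoma of the lung")
        organ, histology = COMBINABLE[profile.cancer_concept]
        cancer_phrase = f"{histology} of the {organ}"
        sentences.append(
            f"The patient is a {age}-year-old {sex} with {met}{cancer_phrase}."
        )
    elif profile.cancer_concept in COMBINABLE and variant < 0.5:
        # organ and histology as separate mentions in one sentence, which
        # only the organ+histology combination step can resolve
        organ, histology = COMBINABLE[profile.cancer_concept]
        cancer_phrase = histology
        sentences.append(
            f"The patient is a {age}-year-old {sex}; biopsy of the {organ} "
            f"confirmed {met}{histology}."
        )
    else:
        cancer_phrase = name
        sentences.append(
            f"The patient is a {age}-year-old {sex} with {met}{cancer_phrase}."
        )
    plants.append(("cancer", profile.cancer_concept, cancer_phrase))
    if profile.metastatic and rng.random() < 0.5:
        sentences.append("Staging studies confirmed metastatic spread to distant sites.")

    in_mm = "size_in_mm" in profile.confounders
    for category, dims in profile.lesions:
        if category == "solid_organ":
            site = rng.choice(_SOLID_SITES)
        elif category == "lymph_node":
            site = rng.choice(_NODE_SITES)
        else:
            site = rng.choice(_BONE_SITES)
        size = _render_size(dims, in_mm, rng)
        template = rng.choice(
            [
                f"CT imaging demonstrated a {size} lesion in the {site}.",
                f"A {site} lesion measuring {size} was noted on imaging.",
            ]
        )
        sentences.append(template)
        plants.append(("lesion", f"{category}:{max(dims):.1f}", size))

    if profile.ecog_rendering == "explicit":
        phrase = rng.choice(
            [
                f"ECOG performance status is {profile.ecog}.",
                f"ECOG performance status: {profile.ecog}.",
                f"Current ECOG PS is {profile.ecog}.",
            ]
        )
        sentences.append(phrase)
        plants.append(("ecog", str(profile.ecog), phrase))
    elif profile.ecog_rendering == "implicit_good":
        phrase = rng.choice(
            [
                "The patient remains active and continues to work.",
                "Overall the patient is doing well.",
                "The patient reports being in good health.",
            ]
        )
        sentences.append(phrase)
        plants.append(("ecog_implicit", "good", phrase))
    elif profile.ecog_rendering == "implicit_poor":
        phrase = rng.choice(
            [
                "The patient is now mostly bed bound.",
                "The patient is wheelchair bound and often fatigued.",
                "The family reports limited activity at home.",
            ]
        )
        sentences.append(phrase)
        plants.append(("ecog_implicit", "poor", phrase))

    if profile.mutations:
        tokens = list(profile.mutations)
        if "gene_synonym_swap" in profile.confounders:
            tokens = [_SWAP_RENDER.get(t, t) for t in tokens]
        if "expression_variant" in profile.confounders:
            tokens = [f"{tokens[0]} mut"] + tokens[1:]
        sentences.append(
            "Next-generation sequencing identified pathogenic alterations in "
            f"{_join_tokens(tokens)}."
        )
        for t in tokens:
            plants.append(("mutation", t, t))
    else:
        sentences.append("Genomic profiling was unrevealing.")

    for gene in profile.therapy_mentions:
        sentences.append(
            rng.choice(
                [
                    f"The patient previously received anti-{gene} therapy.",
                    f"Prior treatment included {gene}-targeted therapy.",
                ]
            )
        )
        plants.append(("therapy", gene, gene))

    if "negated_cancer" in profile.confounders:
        others = [c for c in PATIENT_CANCERS if c != profile.cancer_concept]
        distractor = index.name_of(rng.choice(others)).lower()
        sentences.append(f"Workup showed no evidence of {distractor}.")
        plants.append(("negated_cancer", distractor, distractor))

    text = " ".join(sentences)
    annotations = {
        "profile": _profile_dict(profile),
        "planted": _locate_plants(text, plants),
    }
    return text, annotations


def render_protocol(
    profile: ProtocolProfile, seed: int, index: OntologyIndex | None = None
) -> tuple[str, dict]:
    """Deterministic protocol text with Inclusion/Exclusion sections.

    Criteria render in seeded template variants (bulleted or prose;
    "ECOG performance status 0-1" vs "<= 1"; RECIST phrasing), covering
    the layouts real protocols use.
    """
    index = index or load_default_index()
    rng = random.Random(f"protocol-render:{seed}")
    drug = rng.choice(["ABC-123", "XT-774", "QL-921", "MK-4412", "NV-058"])
    title = f"A Phase 1 Study of {drug} in Subjects with Advanced Disease."

    inclusion: list[str] = []
    if profile.required_cancer:
        met = "metastatic " if profile.requires_metastatic else ""
        name = index.name_of(profile.required_cancer).lower()
        inclusion.append(f"Histologically confirmed {met}{name}.")
    if profile.ecog_requirement:
        req = profile.ecog_requirement
        if req.comparator == "range":
            inclusion.append(
                rng.choice(
                    [
                        f"ECOG performance status {req.bound_low}-{req.bound_high}.",
                        f"ECOG performance status of {req.bound_low}-{req.bound_high}.",
                    ]
                )
            )
        elif req.comparator == "le":
            inclusion.append(
                rng.choice(
                    [
                        f"ECOG performance status ≤ {req.bound_high}.",
                        f"ECOG performance status <= {req.bound_high}.",
                    ]
                )
            )
        elif req.comparator == "ge":
            inclusion.append(f"ECOG performance status ≥ {req.bound_low}.")
        else:
            inclusion.append(f"ECOG performance status = {req.bound_high}.")
    if profile.requires_measurable:
        inclusion.append(
            rng.choice(
                [
                    "Measurable disease per RECIST v1.1.",
                    "At least one lesion measuring 1 cm or greater in the longest dimension.",
                ]
            )
        )
    if profile.required_mutations:
        genes = ", ".join(profile.required_mutations)
        inclusion.append(
            "A known pathogenic mutation in any of the following genes: "
            f"{genes}."
        )
    if "undefined_abbrev" in profile.confounders:
        inclusion.append(_LIVER_FUNCTION_LINE)
    inclusion.append("Age 18 years or older.")
    inclusion.append("Adequate organ function and a life expectancy of at least 12 weeks.")

    exclusion = list(profile.exclusion_items) or ["None specified."]

    bulleted = rng.random() < 0.6
    if bulleted:
        inc_block = "\n".join(f"- {item}" for item in inclusion)
        exc_block = "\n".join(f"- {item}" for item in exclusion)
    else:
        inc_block = " ".join(inclusion)
        exc_block = " ".join(exclusion)
    text = (
        f"{title}\n"
        "Inclusion Criteria:\n"
        f"{inc_block}\n"
        "Exclusion Criteria:\n"
        f"{exc_block}\n"
    )
    annotations = {
        "profile": _protocol_dict(profile),
        "layout": "bulleted" if bulleted else "prose",
    }
    return text, annotations


def _locate_plants(text: str, plants: list[tuple[str, str, str]]) -> list[dict]:
    located = []
    cursor = 0
    for kind, value, needle in plants:
        pos = text.find(needle, cursor)
        if pos == -1:
            pos = text.find(needle)
        span = [pos, pos + len(needle)] if pos != -1 else None
        located.append({"kind": kind, "value": value, "span": span})
        if pos != -1:
            cursor = pos
    return located


def _profile_dict(p: PatientProfile) -> dict:
    return {
        "cancer_concept": p.cancer_concept,
        "metastatic": p.metastatic,
        "ecog": p.ecog,
        "ecog_rendering": p.ecog_rendering,
        "lesions": [[c, list(d)] for c, d in p.lesions],
        "mutations": list(p.mutations),
        "therapy_mentions": list(p.therapy_mentions),
        "confounders": sorted(p.confounders),
    }


def _protocol_dict(p: ProtocolProfile) -> dict:
    req = p.ecog_requirement
    return {
        "required_cancer": p.required_cancer,
        "requires_metastatic": p.requires_metastatic,
        "ecog_requirement": (
            {"comparator": req.comparator, "low": req.bound_low, "high": req.bound_high}
            if req
            else None
        ),
        "requires_measurable": p.requires_measurable,
        "required_mutations": list(p.required_mutations),
        "exclusion_items": list(p.exclusion_items),
        "confounders": sorted(p.confounders),
    }


# -- profile sampling -----------------------------------------------------


def sample_protocol(rng: random.Random, index: OntologyIndex) -> ProtocolProfile:
    n_req = rng.choices([1, 2, 3, 4], weights=[0.15, 0.3, 0.25, 0.3])[0]
    chosen = rng.sample(["cancer", "ecog", "measurable", "mutation"], n_req)
    required_cancer = None
    requires_metastatic = False
    if "cancer" in chosen:
        required_cancer = rng.choice(PROTOCOL_CANCERS)
        requires_metastatic = rng.random() < 0.5
    ecog_requirement = None
    if "ecog" in chosen:
        ecog_requirement = rng.choice(
            [
                ECOGRequirement("le", 0, 1, (0, 0)),
                ECOGRequirement("le", 0, 2, (0, 0)),
                ECOGRequirement("range", 0, 1, (0, 0)),
                ECOGRequirement("range", 0, 2, (0, 0)),
            ]
        )
    required_mutations: list[str] = []
    if "mutation" in chosen:
        required_mutations = rng.sample(MUTATION_POOL, rng.randint(2, 4))
    exclusion_items = rng.sample(_GENERIC_EXCLUSIONS, rng.randint(1, 2))
    if rng.random() < 0.3:
        name = index.name_of(rng.choice(PATIENT_CANCERS)).lower()
        exclusion_items.append(f"Patients with {name} are not eligible.")
    return ProtocolProfile(
        required_cancer=required_cancer,
        requires_metastatic=requires_metastatic,
        ecog_requirement=ecog_requirement,
        requires_measurable="measurable" in chosen,
        required_mutations=required_mutations,
        exclusion_items=exclusion_items,
    )


def _sample_lesion(rng: random.Random, category: str | None = None):
    category = category or rng.choices(
        ["solid_organ", "lymph_node", "bone"], weights=[0.5, 0.3, 0.2]
    )[0]
    n_dims = rng.choice([1, 2, 3])
    dims = tuple(
        sorted((round(rng.uniform(0.4, 4.0), 1) for _ in range(n_dims)), reverse=True)
    )
    return category, dims


def sample_patient(
    rng: random.Random,
    protocols: list[ProtocolProfile],
    index: OntologyIndex,
    max_tries: int = 2000,
) -> PatientProfile:
    """Sample a patient decisive against every protocol (see module doc)."""
    for _ in range(max_tries):
        anchor = rng.choice(protocols)

        if anchor.required_cancer:
            pool = [
                c
                for c in PATIENT_CANCERS
                if _is_descendant(index, c, anchor.required_cancer)
            ] or PATIENT_CANCERS
            cancer = rng.choice(pool)
            metastatic = True if anchor.requires_metastatic else rng.random() < 0.55
        else:
            cancer = rng.choice(PATIENT_CANCERS)
            metastatic = rng.random() < 0.55

        if anchor.ecog_requirement:
            ecog = rng.choice(sorted(anchor.ecog_requirement.admissible_levels()))
        else:
            ecog = rng.choices([0, 1, 2, 3, 4], weights=[3, 4, 3, 2, 1])[0]
        if ecog <= 1:
            rendering = rng.choices(
                ["explicit", "implicit_good", "absent"], weights=[5, 3, 1]
            )[0]
        else:
            rendering = rng.choices(
                ["explicit", "implicit_poor", "absent"], weights=[5, 3, 1]
            )[0]

        lesions = [_sample_lesion(rng) for _ in range(rng.randint(0, 2))]
        if anchor.requires_measurable:
            lesions.append(
                ("solid_organ", tuple(sorted(
                    (round(rng.uniform(1.2, 4.0), 1) for _ in range(rng.choice([1, 2]))),
                    reverse=True,
                )))
            )

        mutations: list[str] = []
        if anchor.required_mutations:
            mutations = rng.sample(
                anchor.required_mutations,
                min(len(anchor.required_mutations), rng.randint(1, 2)),
            )
        extra_pool = [g for g in MUTATION_POOL if g not in mutations]
        mutations += rng.sample(extra_pool, rng.randint(0, 2))
        if not anchor.required_mutations and rng.random() < 0.35:
            mutations = []
        therapy = (
            rng.sample([g for g in THERAPY_GENES if g not in mutations], 1)
            if rng.random() < 0.4
            else []
        )

        candidate = PatientProfile(
            cancer_concept=cancer,
            metastatic=metastatic,
            ecog=ecog,
            ecog_rendering=rendering,
            lesions=lesions,
            mutations=mutations,
            therapy_mentions=therapy,
        )
        if all(_is_decisive(candidate, q, index) for q in protocols):
            return candidate
    raise RuntimeError("could not sample a decisive patient profile")


# -- corpus ---------------------------------------------------------------


@dataclass
class SynthDoc:
    id: str
    kind: str
    text: str
    profile: PatientProfile | ProtocolProfile
    annotations: dict


@dataclass
class CorpusBundle:
    patients: list[SynthDoc]
    protocols: list[SynthDoc]
    gold: dict[tuple[str, str], str]
    seed: int

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(p.id, q.id) for p in self.patients for q in self.protocols]

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for doc in self.patients + self.protocols:
            path = out / f"{doc.id}.txt"
            path.write_text(doc.text, encoding="utf-8")
            manifest.append({"id": doc.id, "kind": doc.kind, "path": path.name})
        with open(out / "gold_labels.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient_id", "protocol_id", "label"])
            for (pid, qid), label in sorted(self.gold.items()):
                writer.writerow([pid, qid, label])
        annotations = {
            doc.id: doc.annotations for doc in self.patients + self.protocols
        }
        (out / "annotations.json").write_text(
            json.dumps(annotations, indent=2, ensure_ascii=False), encoding="utf-8"
        )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
        return {"manifest": manifest, "out_dir": str(out)}


def _derived_seed(seed: int, label: str) -> int:
    return zlib.crc32(f"{seed}:{label}".encode()) % (2**31)


def generate_corpus(
    n_patients: int = 12,
    n_protocols: int = 6,
    confounder_rates: dict[str, float] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    index: OntologyIndex | None = None,
) -> CorpusBundle:
    """Generate a fully gold-labelled corpus (defaults: 12 patients x 6
    protocols = 72 pairs).

    ``confounder_rates`` maps confounder name -> probability per document.
    Confounder draws use RNG streams independent of profile sampling, so
    raising a rate perturbs only the affected documents' renderings.
    Profiles, texts, labels and annotations are all reproducible from
    ``seed``.
    """
    if n_patients < 1 or n_protocols < 1:
        raise ValueError("n_patients and n_protocols must be >= 1")
    confounder_rates = confounder_rates or {}
    unknown = set(confounder_rates) - CONFOUNDERS
    if unknown:
        raise ValueError(f"unknown confounders: {sorted(unknown)}")
    index = index or load_default_index()

    protocols: list[SynthDoc] = []
    protocol_profiles: list[ProtocolProfile] = []
    for j in range(n_protocols):
        rng = random.Random(f"{seed}:protocol:{j}")
        profile = sample_protocol(rng, index)
        conf_rng = random.Random(f"{seed}:conf:protocol:{j}")
        applied = set()
        # undefined_abbrev is a protocol-side confounder (an ALT-style
        # laboratory criterion); the patient-side confounders do not apply.
        if conf_rng.random() < confounder_rates.get("undefined_abbrev", 0.0):
            applied.add("undefined_abbrev")
        profile = replace(profile, confounders=frozenset(applied))
        protocol_profiles.append(profile)
        text, ann = render_protocol(
            profile, _derived_seed(seed, f"protocol:{j}"), index
        )
        ann["applied_confounders"] = sorted(applied)
        protocols.append(SynthDoc(f"T{j + 1}", "protocol", text, profile, ann))

    patients: list[SynthDoc] = []
    patient_profiles: list[PatientProfile] = []
    for i in range(n_patients):
        rng = random.Random(f"{seed}:patient:{i}")
        profile = sample_patient(rng, protocol_profiles, index)
        conf_rng = random.Random(f"{seed}:conf:patient:{i}")
        applied = set()
        for name in sorted(CONFOUNDERS - {"undefined_abbrev"}):
            if conf_rng.random() < confounder_rates.get(name, 0.0):
                applied.add(name)
        # a confounder with nothing to act on is not recorded as applied
        if "gene_synonym_swap" in applied and not (
            set(profile.mutations) & set(_SWAP_RENDER)
        ):
            applied.discard("gene_synonym_swap")
        if "expression_variant" in applied and not profile.mutations:
            applied.discard("expression_variant")
        if "size_in_mm" in applied and not profile.lesions:
            applied.discard("size_in_mm")
        profile = replace(profile, confounders=frozenset(applied))
        patient_profiles.append(profile)
        text, ann = render_patient(profile, _derived_seed(seed, f"patient:{i}"), index)
        ann["applied_confounders"] = sorted(applied)
        patients.append(SynthDoc(f"P{i + 1}", "patient", text, profile, ann))

    gold = {
        (p.id, q.id): gold_label(pp, qp, index)
        for p, pp in zip(patients, patient_profiles)
        for q, qp in zip(protocols, protocol_profiles)
    }
    bundle = CorpusBundle(patients=patients, protocols=protocols, gold=gold, seed=seed)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
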