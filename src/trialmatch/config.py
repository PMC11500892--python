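"""Configuration surface: lexicons, thresholds, site tables, gene synonyms.

Every rule the matcher applies lives here with a documented default, and a
single YAML/JSON file can override any of it, so the whole behaviour of the
system is auditable in one place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

from .tagging import Lexicon
from .textprep import DEFAULT_NEGATION_TRIGGERS
from .ontology import OntologyIndex, load_default_index

# -- criterion lexicons ---------------------------------------------------

#: phrases describing good functional status (implicit ECOG 0-1)
GOOD_HEALTH_PHRASES = [
    "active",
    "doing well",
    "in good health",
    "fully functional",
    "asymptomatic",
]

#: phrases describing poor functional status (implicit ECOG 2-4)
POOR_HEALTH_PHRASES = [
    "fatigued",
    "wheelchair bound",
    "limited activity",
    "bed bound",
    "bedridden",
]

#: anatomic-site keyword -> measurability category
DEFAULT_SITE_MAP = {
    "liver": "solid_organ",
    "lung": "solid_organ",
    "kidney": "solid_organ",
    "spleen": "solid_organ",
    "pancreas": "solid_organ",
    "adrenal gland": "solid_organ",
    "lymph node": "lymph_node",
    "lymph nodes": "lymph_node",
    "bone": "bone",
    "vertebra": "bone",
    "femur": "bone",
    "iliac bone": "bone",
    "rib": "bone",
    "spine": "bone",
}

#: organ words used for organ+histology combination in cancer-type extraction
ORGAN_WORDS = [
    "lung",
    "liver",
    "pancreas",
    "colon",
    "rectum",
    "stomach",
    "breast",
    "prostate",
    "ovary",
    "kidney",
    "bladder",
    "esophagus",
    "cervix",
    "thyroid",
    "skin",
    "appendix",
    "brain",
]

METASTASIS_CUES = ["metastatic", "metastases", "metastasis"]

#: gene symbols recognised by the built-in tagger
GENES = [
    "ARID1A", "ATM", "ATR", "BRCA1", "BRCA2", "PALB2", "RAD51", "RAD51B",
    "RAD54L", "CHK2", "CHEK2", "TP53", "KRAS", "NRAS", "EGFR", "PIK3CA",
    "HER2", "ERBB2", "VEGF", "FANCA", "MLH1", "MSH2", "BRIP1", "BARD1",
    "CDK12", "FGFR2", "IDH1", "ALK", "ROS1", "MET", "BRAF",
]

#: tags treated as cancer-type evidence / mutation evidence
DISEASE_TAGS = {"disease"}
MUTATION_TAGS = {"gene", "mutation", "DNA"}


def load_gene_synonyms() -> dict[str, str]:
    """Lowercased token -> canonical token (packaged TSV table).

    Covers true gene synonyms (CHEK2 = CHK2, ERBB2 = HER2) and
    expression-variant forms ("BRCA1 mut" -> BRCA1).  The matcher only
    consults this table when synonym resolution is switched on; by default
    mutation matching is exact-token.
    """
    table: dict[str, str] = {}
    data = resources.files("trialmatch.data").joinpath("gene_synonyms.tsv")
    for line in data.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        variant, canonical = line.split("\t")[:2]
        table[variant.strip().lower()] = canonical.strip().lower()
    return table


def build_default_lexicon(index: OntologyIndex) -> Lexicon:
    """Dictionary for the built-in tagger.

    Disease entries come from every ontology preferred name and synonym
    (including blocklisted generic concepts — those are tagged and then
    dropped at concept mapping, reproducing the generic-concept exclusion);
    organ, metastasis-cue and gene entries come from the module tables.
    """
    entries: dict[str, str] = {}
    for concept in index.concepts.values():
        entries[concept.preferred_name.lower()] = "disease"
        for syn in concept.synonyms:
            entries[syn.lower()] = "disease"
    for organ in ORGAN_WORDS:
        entries.setdefault(organ, "organ")
    for cue in METASTASIS_CUES:
        entries.setdefault(cue, "Metastasis")
    for gene in GENES:
        entries[gene.lower()] = "gene"
        entries[f"{gene.lower()} mut"] = "gene"
    return Lexicon(entries)


@dataclass
class RunConfig:
    """Tunable parameters, each with the shipped default.

    ``threshold`` is the strict decision cut-off (score must exceed it);
    ``measurability_inclusive`` selects >= (RECIST reading) vs > for the
    1 cm / 1.5 cm lesion cut-offs; ``synonym_table_enabled`` turns on gene
    synonym canonicalisation (off by default: exact-token matching).
    """

    threshold: float = 0.5
    synonym_table_enabled: bool = False
    indeterminate_as_no_match: bool = False
    measurability_inclusive: bool = True
    rectify_window: int = 40
    negation_triggers: list[str] = field(
        default_factory=lambda: list(DEFAULT_NEGATION_TRIGGERS)
    )
    good_health_phrases: list[str] = field(default_factory=lambda: list(GOOD_HEALTH_PHRASES))
    poor_health_phrases: list[str] = field(default_factory=lambda: list(POOR_HEALTH_PHRASES))
    site_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SITE_MAP))
    ontology_path: str | None = None
    lexicon_path: str | None = None
    synonym_table_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must lie in [0, 1)")
        if self.rectify_window <= 0:
            raise ValueError("rectify_window must be positive")


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML or JSON config file, overlaying the defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(raw) or {}
    else:
        data = json.loads(raw)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
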