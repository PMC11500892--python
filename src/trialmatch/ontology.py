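"""Neoplasm-branch concept store: normalization, lookup, subtype queries.

The concept store mirrors the shape of the NCI Thesaurus "Neoplasm" branch
(root code C3262): each concept has a code, a preferred name, synonyms and
one or more parent codes (the branch is a DAG, not a tree).  A compact
fixture thesaurus ships with the package; the same flat TSV dialect loads a
real thesaurus export.

Name matching is deliberately word-order-insensitive: terms are lowercased,
punctuation is stripped and the words are sorted alphabetically before
lookup, so "adenocarcinoma of the lung" and "Lung Adenocarcinoma" meet at
the same key.  Lookup is two-tiered — preferred names first, synonyms as a
fallback — and a small blocklist of uninformative generic concepts
("Malignant Neoplasm", "Solid Neoplasm", "Metastatic Neoplasm", and the
bare root) never maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

#: Codes excluded from concept mapping because they carry no information
#: for trial matching (the generic-concept exclusion).
DEFAULT_BLOCKLIST = frozenset({"C3262", "C9305", "C9292", "C3520"})

_PUNCT_RE = re.compile(r"[^a-z0-9]+")


def normalize_term(term: str) -> str:
    """Lowercase, strip punctuation, sort words alphabetically.

    Raises ``ValueError`` for empty/whitespace-only input.
    """
    if not term or not term.strip():
        raise ValueError("term must be non-empty")
    words = _PUNCT_RE.sub(" ", term.lower()).split()
    if not words:
        raise ValueError(f"term {term!r} has no alphanumeric content")
    return " ".join(sorted(words))


@dataclass(frozen=True)
class Concept:
    code: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()


@dataclass
class OntologyIndex:
    concepts: dict[str, Concept]
    preferred_index: dict[str, str] = field(default_factory=dict)
    synonym_index: dict[str, list[str]] = field(default_factory=dict)
    generic_blocklist: frozenset[str] = DEFAULT_BLOCKLIST

    def __post_init__(self) -> None:
        for code, concept in self.concepts.items():
            if not concept.preferred_name:
                raise ValueError(f"concept {code} has an empty preferred name")
            for parent in concept.parents:
                if parent not in self.concepts:
                    raise ValueError(f"concept {code} has dangling parent {parent}")
        for code in self.generic_blocklist:
            if code not in self.concepts:
                raise ValueError(f"blocklist code {code} not in concept store")
        self._check_acyclic()
        if not self.preferred_index:
            self._build_indexes()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {c: WHITE for c in self.concepts}
        for root in self.concepts:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(root, 0)]
            color[root] = GREY
            while stack:
                node, i = stack[-1]
                parents = self.concepts[node].parents
                if i < len(parents):
                    stack[-1] = (node, i + 1)
                    nxt = parents[i]
                    if color[nxt] == GREY:
                        raise ValueError(f"cycle through concept {nxt}")
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    color[node] = BLACK
                    stack.pop()

    def _build_indexes(self) -> None:
        for code, concept in self.concepts.items():
            self.preferred_index[normalize_term(concept.preferred_name)] = code
            for syn in concept.synonyms:
                key = normalize_term(syn)
                codes = self.synonym_index.setdefault(key, [])
                if code not in codes:
                    codes.append(code)

    # -- queries ---------------------------------------------------------

    def ancestors(self, code: str) -> set[str]:
        """All proper ancestors of ``code`` via parent edges."""
        if code not in self.concepts:
            raise ValueError(f"unknown concept code {code!r}")
        seen: set[str] = set()
        frontier = list(self.concepts[code].parents)
        while frontier:
            cur = frontier.pop()
            if cur in seen:
                continue
            seen.add(cur)
            frontier.extend(self.concepts[cur].parents)
        return seen

    def descendants(self, code: str) -> set[str]:
        if code not in self.concepts:
            raise ValueError(f"unknown concept code {code!r}")
        children: dict[str, list[str]] = {}
        for c, concept in self.concepts.items():
            for p in concept.parents:
                children.setdefault(p, []).append(c)
        seen: set[str] = set()
        frontier = list(children.get(code, []))
        while frontier:
            cur = frontier.pop()
            if cur in seen:
                continue
            seen.add(cur)
            frontier.extend(children.get(cur, []))
        return seen

    def name_of(self, code: str) -> str:
        return self.concepts[code].preferred_name

    @classmethod
    def from_tsv(
        cls, path: str | Path, blocklist: frozenset[str] | set[str] | None = None
    ) -> "OntologyIndex":
        """Load the flat dialect: ``code<TAB>preferred_name<TAB>synonyms``
        (``|``-separated) ``<TAB>parents`` (``|``-separated)."""
        concepts: dict[str, Concept] = {}
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:  # skip header
            if not line.strip() or line.startswith("#"):
                continue
            parts = (line.split("\t") + ["", "", "", ""])[:4]
            code, name, syns, parents = (p.strip() for p in parts)
            if code in concepts:
                raise ValueError(f"duplicate concept code {code}")
            concepts[code] = Concept(
                code=code,
                preferred_name=name,
                synonyms=tuple(s for s in syns.split("|") if s),
                parents=tuple(p for p in parents.split("|") if p),
            )
        return cls(
            concepts=concepts,
            generic_blocklist=frozenset(blocklist) if blocklist is not None else DEFAULT_BLOCKLIST,
        )


def load_default_index() -> OntologyIndex:
    """The packaged fixture mini-thesaurus (root C3262)."""
    with resources.as_file(
        resources.files("trialmatch.data").joinpath("ontology.tsv")
    ) as path:
        return OntologyIndex.from_tsv(path)


def map_to_concept(term: str, index: OntologyIndex) -> str | None:
    """Two-tier lookup of a surface term; None is a value, not an error.

    Tier 1 consults preferred names, tier 2 synonyms.  A blocklisted hit
    returns None.  A tier-2 multi-hit resolves fewest-parents-first, then
    lexicographic code, so the result is deterministic.
    """
    try:
        key = normalize_term(term)
    except ValueError:
        return None
    code = index.preferred_index.get(key)
    if code is not None:
        return None if code in index.generic_blocklist else code
    candidates = [
        c for c in index.synonym_index.get(key, []) if c not in index.generic_blocklist
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (len(index.concepts[c].parents), c))


def is_subtype(child: str, ancestor: str, index: OntologyIndex) -> bool:
    """True iff ``ancestor`` is reachable from ``child`` (reflexive)."""
    if child not in index.concepts:
        raise ValueError(f"unknown concept code {child!r}")
    if ancestor not in index.concepts:
        raise ValueError(f"unknown concept code {ancestor!r}")
    if child == ancestor:
        return True
    return ancestor in index.ancestors(child)
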