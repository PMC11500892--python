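"""Abbreviation normalization and negation flagging.

Clinical text defines a term once and then uses its parenthesized acronym —
"response evaluation criteria in solid tumors (RECIST)".  We recover these
definitions with Schwartz–Hearst style initial-letter back-scanning and
substitute the long form for every later use of the short form, because the
downstream concept lookup only knows full names.  An acronym that is *never*
defined in the document stays unexpanded; whatever the ontology then makes
of it is an honest (and clinically documented) failure mode.

Negation is the simplified sentence-scope rule: if any trigger phrase
("except for", "no evidence of", ...) occurs in a sentence, every mention
in that sentence is flagged negated.  This is intentionally cruder than
full NegEx pre/post windows; scope direction is not modelled.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

from .documents import Document, Span
from .tagging import EntityMention

DEFAULT_NEGATION_TRIGGERS = [
    "not including",
    "except for",
    "no evidence of",
    "without",
    "denies",
    "no history of",
    "absence of",
    "ruled out",
    "negative for",
]

_FUNCTION_WORDS = {"of", "in", "the", "and", "for", "with", "on", "to", "a", "an"}


@dataclass
class AbbreviationMap:
    """short form -> (long form, span of its first parenthetical definition)."""

    entries: dict[str, tuple[str, Span]] = field(default_factory=dict)

    def long_form(self, short: str) -> str | None:
        hit = self.entries.get(short)
        return hit[0] if hit else None

    def to_dict(self) -> dict[str, str]:
        return {k: v[0] for k, v in self.entries.items()}


@dataclass
class NegationConfig:
    trigger_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATION_TRIGGERS))

    def __post_init__(self) -> None:
        cleaned = [t.strip().lower() for t in self.trigger_patterns]
        if any(not t for t in cleaned):
            raise ValueError("negation trigger patterns must be non-empty")
        self.trigger_patterns = cleaned


_PAREN_RE = re.compile(r"\(([^()]{2,10})\)")


def _find_best_long_form(short: str, candidate: str) -> str | None:
    """Schwartz–Hearst right-to-left character matching.

    Each alphanumeric character of ``short`` must appear, in order, in
    ``candidate``; the first character must sit at a word start.  Returns
    the matched suffix of ``candidate`` or None.
    """
    letters = [c.lower() for c in short if c.isalnum()]
    if not letters:
        return None
    low = candidate.lower()
    si = len(letters) - 1
    li = len(low) - 1
    while si >= 0:
        c = letters[si]
        while li >= 0:
            at_word_start = li == 0 or not low[li - 1].isalnum()
            if low[li] == c and (si > 0 or at_word_start):
                break
            li -= 1
        if li < 0:
            return None
        si -= 1
        li -= 1
    long_form = candidate[li + 1:].strip()
    return long_form or None


def detect_abbreviations(doc: Document) -> AbbreviationMap:
    """Collect ``LONG FORM (SHORT)`` definitions, first occurrence only.

    A candidate short form is 2-10 characters, contains no whitespace, and
    at least half of its letters are uppercase (which rejects lesion-size
    parentheticals like "(2.3 x 1.1)").  The long form is recovered from
    the words preceding the parenthesis within the same sentence.
    """
    text = doc.raw_text
    amap = AbbreviationMap()
    for m in _PAREN_RE.finditer(text):
        short = m.group(1).strip()
        if not 2 <= len(short) <= 10 or any(ch.isspace() for ch in short):
            continue
        alpha = [c for c in short if c.isalpha()]
        if not alpha or sum(c.isupper() for c in alpha) / len(alpha) < 0.5:
            continue
        if short in amap.entries:
            continue
        sent_idx = doc.sentence_index(m.start())
        sent_start = doc.sentences[sent_idx][0] if sent_idx >= 0 else 0
        pre = text[sent_start:m.start()].rstrip()
        words = re.findall(r"\S+", pre)
        n_chars = len([c for c in short if c.isalnum()])
        k = min(n_chars + 5, n_chars * 2)
        candidate = " ".join(words[-k:]) if words else ""
        if not candidate:
            continue
        long_form = _find_best_long_form(short, candidate)
        if long_form:
            amap.entries[short] = (long_form, (m.start(1), m.end(1)))
    return amap


def expand_mentions(
    mentions: list[EntityMention], abbrev: AbbreviationMap
) -> list[EntityMention]:
    """Attach ``expanded_surface`` to mentions of known short forms.

    The defining parenthetical occurrence itself is left unexpanded.
    """
    if not abbrev.entries:
        return list(mentions)
    out: list[EntityMention] = []
    for m in mentions:
        hit = abbrev.entries.get(m.surface)
        if hit and (m.start, m.end) != hit[1]:
            out.append(dataclasses.replace(m, expanded_surface=hit[0]))
        else:
            out.append(m)
    return out


def flag_negation(
    doc: Document, mentions: list[EntityMention], config: NegationConfig | None = None
) -> list[EntityMention]:
    """Sentence-scope negation: mark every mention in a trigger sentence.

    Only the ``negated`` flag changes; spans, surfaces and tags are
    untouched.
    """
    config = config or NegationConfig()
    negated_sentences: list[Span] = []
    for s, e in doc.sentences:
        sent = doc.raw_text[s:e].lower()
        if any(t in sent for t in config.trigger_patterns):
            negated_sentences.append((s, e))
    if not negated_sentences:
        return list(mentions)
    out: list[EntityMention] = []
    for m in mentions:
        inside = any(s <= m.start and m.end <= e for s, e in negated_sentences)
        out.append(dataclasses.replace(m, negated=True) if inside and not m.negated else m)
    return out
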