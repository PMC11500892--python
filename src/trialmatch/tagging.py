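"""Entity tagging: a pluggable tagger contract plus the multi-tagger merge.

External NER taggers participate through the :class:`TaggerOutput` contract
(one JSON-lines record per mention); the built-in :func:`tag_with_lexicon`
tagger covers the same role with a longest-match-first dictionary scan, so
the pipeline runs without any model download.

Taggers frequently disagree on character offsets (different text encodings
or tokenisers), so before merging, every mention is *rectified*: if the
claimed span does not reproduce the surface string, the raw text is searched
within a +/-40-character window around the claimed start and the nearest
occurrence wins.  Mentions whose surface cannot be found in the window are
flagged unrectifiable and dropped from the merge.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .documents import Document, Span

DEFAULT_RECTIFY_WINDOW = 40


@dataclass(frozen=True)
class EntityMention:
    """A tagged text span.

    ``tags`` is a tuple of ``(tag_label, tagger_name)`` pairs: after the
    merge a single span can carry one tag from each tagger that found it.
    ``expanded_surface``, when set by abbreviation normalization, is what
    downstream matching uses instead of the raw surface.
    """

    surface: str
    start: int
    end: int
    tags: tuple[tuple[str, str], ...]
    negated: bool = False
    expanded_surface: str | None = None
    unrectifiable: bool = False

    @property
    def span(self) -> Span:
        return (self.start, self.end)

    @property
    def matching_surface(self) -> str:
        """Surface used for concept/token matching (expansion-aware)."""
        return self.expanded_surface if self.expanded_surface else self.surface

    def tag_labels(self) -> set[str]:
        return {t for t, _ in self.tags}


@dataclass
class TaggerOutput:
    tagger_name: str
    mentions: list[EntityMention] = field(default_factory=list)


@dataclass
class Lexicon:
    """Surface-string -> tag dictionary backing the built-in tagger.

    Keys are lowercase with collapsed whitespace; values are tag labels such
    as ``disease``, ``organ``, ``gene`` or ``Metastasis``.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for key, tag in self.entries.items():
            norm = re.sub(r"\s+", " ", key.strip().lower())
            if not norm:
                raise ValueError("lexicon keys must be non-empty")
            cleaned[norm] = tag
        self.entries = cleaned

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            surface, tag = line.split("\t")[:2]
            entries[surface] = tag
        return cls(entries)


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def tag_with_lexicon(
    doc: Document,
    lexicon: Lexicon,
    tagger_name: str = "lexicon",
    max_ngram: int = 6,
) -> TaggerOutput:
    """Case-insensitive longest-match-first scan over token n-grams (n<=6).

    The candidate surface for an n-gram is the raw text slice between the
    first and last token, with whitespace collapsed, so hyphenated lexicon
    entries ("non-small cell lung carcinoma") match as written.  Matches
    never overlap within this tagger.
    """
    if not lexicon.entries:
        raise ValueError("lexicon must be non-empty")
    text = doc.raw_text
    tokens = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(max_ngram, len(tokens) - i), 0, -1):
            s = tokens[i][0]
            e = tokens[i + n - 1][1]
            cand = re.sub(r"\s+", " ", text[s:e].lower())
            tag = lexicon.entries.get(cand)
            if tag is not None:
                hit = (s, e, tag, n)
                break
        if hit is None:
            i += 1
            continue
        s, e, tag, n = hit
        mentions.append(
            EntityMention(surface=text[s:e], start=s, end=e, tags=((tag, tagger_name),))
        )
        i += n
    return TaggerOutput(tagger_name=tagger_name, mentions=mentions)


def rectify_offsets(
    mention: EntityMention, raw_text: str, window: int = DEFAULT_RECTIFY_WINDOW
) -> EntityMention:
    """Correct a mention's span so ``raw_text[start:end] == surface``.

    The surface is searched within ``window`` characters of the claimed
    start (case-sensitive first, then case-insensitive); among several
    occurrences the one with the smallest offset correction wins.  When the
    surface is absent from the window the mention is returned flagged
    ``unrectifiable`` instead of raising.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    surface = mention.surface
    if raw_text[mention.start:mention.end] == surface:
        return mention
    lo = max(0, mention.start - window)
    hi = min(len(raw_text), mention.start + window + len(surface))
    region = raw_text[lo:hi]

    def _closest(hay: str, needle: str) -> int | None:
        best = None
        pos = hay.find(needle)
        while pos != -1:
            cand = lo + pos
            if best is None or abs(cand - mention.start) < abs(best - mention.start):
                best = cand
            pos = hay.find(needle, pos + 1)
        return best

    new_start = _closest(region, surface)
    if new_start is None:
        new_start = _closest(region.lower(), surface.lower())
    if new_start is None:
        return dataclasses.replace(mention, unrectifiable=True)
    return dataclasses.replace(
        mention,
        start=new_start,
        end=new_start + len(surface),
        surface=raw_text[new_start:new_start + len(surface)],
    )


def merge_outputs(
    outputs: list[TaggerOutput],
    raw_text: str,
    window: int = DEFAULT_RECTIFY_WINDOW,
) -> list[EntityMention]:
    """Combine several taggers' mentions by exact (rectified) span.

    Mentions with identical spans collapse into one mention carrying the
    union of their ``(tag, tagger)`` pairs; partially overlapping spans are
    kept separate.  Unrectifiable mentions are dropped.  The result is
    sorted by span.
    """
    groups: dict[Span, list[EntityMention]] = {}
    order: list[Span] = []
    for out in outputs:
        for m in out.mentions:
            r = rectify_offsets(m, raw_text, window=window)
            if r.unrectifiable:
                continue
            key = r.span
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)

    merged: list[EntityMention] = []
    for key in sorted(order):
        members = groups[key]
        tags: list[tuple[str, str]] = []
        for m in members:
            for pair in m.tags:
                if pair not in tags:
                    tags.append(pair)
        expanded = next((m.expanded_surface for m in members if m.expanded_surface), None)
        s, e = key
        merged.append(
            EntityMention(
                surface=raw_text[s:e],
                start=s,
                end=e,
                tags=tuple(tags),
                negated=any(m.negated for m in members),
                expanded_surface=expanded,
            )
        )
    return merged


def read_tagger_jsonl(path: str | Path) -> list[TaggerOutput]:
    """Read the JSON-lines interchange format for external taggers.

    One mention per line: ``{"tagger": str, "surface": str, "start": int,
    "end": int, "tag": str}``.
    """
    by_tagger: dict[str, list[EntityMention]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        by_tagger.setdefault(rec["tagger"], []).append(
            EntityMention(
                surface=rec["surface"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                tags=((rec["tag"], rec["tagger"]),),
            )
        )
    return [
        TaggerOutput(tagger_name=name, mentions=sorted(ms, key=lambda m: m.span))
        for name, ms in by_tagger.items()
    ]
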