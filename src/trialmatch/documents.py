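"""Document model for patient records and trial protocols.

A :class:`Document` wraps a raw text with two lightweight structural layers:
*sections* (a protocol's ``Inclusion Criteria`` / ``Exclusion Criteria``
blocks, plus a ``body`` for everything else) and *sentence spans*.  All
offsets in the package are 0-based, half-open character spans into
``raw_text``; a single convention avoids the cross-tagger offset drift that
multi-tool NER pipelines suffer from.

Sentence boundaries matter downstream: negation scoping, organ+histology
combination and therapy-context checks are all sentence-scoped, so the
splitter is deliberately simple, deterministic and documented rather than
statistical: it breaks at newlines and at ``. ! ?`` followed by whitespace
and an uppercase letter, never inside parentheses, never after a single
capital letter (initials) or a known abbreviation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

Span = tuple[int, int]


class DocumentKind(str, Enum):
    PATIENT = "patient"
    PROTOCOL = "protocol"


class SectionLabel(str, Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    BODY = "body"


@dataclass(frozen=True)
class Section:
    label: SectionLabel
    span: Span  # includes the heading line, so sections tile the document


@dataclass
class Document:
    id: str
    kind: DocumentKind
    raw_text: str
    sections: list[Section] = field(default_factory=list)
    sentences: list[Span] = field(default_factory=list)

    def section_text(self, label: SectionLabel, *, strip_heading: bool = True) -> str:
        """Concatenated text of all sections with ``label``.

        With ``strip_heading`` (default) the heading line itself is removed,
        leaving only the criteria text.
        """
        parts = []
        for sec in self.sections:
            s, e = sec.span
            text = self.raw_text[s:e]
            if strip_heading and sec.label is not SectionLabel.BODY:
                m = _HEADING_RE.match(text)
                if m:
                    text = text[m.end():]
            parts.append(text)
        out = []
        for sec, text in zip(self.sections, parts):
            if sec.label is label:
                out.append(text)
        return "".join(out)

    def sentence_index(self, offset: int) -> int:
        """Index of the sentence whose span contains ``offset`` (or the
        nearest following sentence; -1 when past the last sentence)."""
        for i, (s, e) in enumerate(self.sentences):
            if offset < e:
                return i
        return -1

    def sentence_span(self, index: int) -> Span:
        return self.sentences[index]


_HEADING_RE = re.compile(
    r"^[ \t]*(?P<label>inclusion|exclusion)[ \t]+criteria[ \t]*:?[ \t]*\n?",
    re.IGNORECASE,
)

# words after which a period does not end a sentence
_ABBREV_GUARD = {"dr", "mr", "mrs", "ms", "st", "vs", "e.g", "i.e", "fig", "al", "no"}

_LAST_WORD_RE = re.compile(r"([A-Za-z][A-Za-z.]*)$")


def split_sentences(text: str) -> list[Span]:
    """Rule-based sentence splitting returning trimmed character spans.

    Spans are ordered, non-overlapping and cover every non-whitespace
    character of ``text``.
    """
    n = len(text)
    starts = [0]
    depth = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif ch == "\n":
            depth = 0  # parentheses do not span lines in these documents
            if i + 1 < n:
                starts.append(i + 1)
        elif ch in ".!?" and depth == 0:
            j = i + 1
            while j < n and text[j] in " \t":
                j += 1
            if j > i + 1 and j < n and text[j].isupper():
                m = _LAST_WORD_RE.search(text, 0, i)
                word = m.group(1) if m and m.end() == i else None
                guarded = word is not None and (
                    (len(word) == 1 and word.isupper())
                    or word.lower().rstrip(".") in _ABBREV_GUARD
                    or word.lower() in _ABBREV_GUARD
                )
                if not guarded:
                    starts.append(j)
                    i = j
                    continue
        i += 1

    spans: list[Span] = []
    bounds = starts + [n]
    for k in range(len(bounds) - 1):
        seg_start, seg_end = bounds[k], bounds[k + 1]
        chunk = text[seg_start:seg_end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        s, e = seg_start + lead, seg_end - trail
        if s < e:
            spans.append((s, e))
    return spans


def parse_document(text: str, kind: DocumentKind | str, doc_id: str = "doc") -> Document:
    """Parse raw text into a :class:`Document`.

    Protocols are segmented on case-insensitive, line-anchored
    ``inclusion criteria`` / ``exclusion criteria`` headings (optional
    colon); any text before the first heading becomes a ``body`` section.
    Patient records are a single ``body`` section.

    Raises ``ValueError`` on empty/whitespace-only text or on a protocol
    with a duplicated heading.
    """
    kind = DocumentKind(kind)
    if not text or not text.strip():
        raise ValueError("document text must be non-empty")

    sections: list[Section] = []
    if kind is DocumentKind.PATIENT:
        sections.append(Section(SectionLabel.BODY, (0, len(text))))
    else:
        headings = [
            (m.start(), SectionLabel(m.group("label").lower()))
            for m in re.finditer(
                r"^[ \t]*(?P<label>inclusion|exclusion)[ \t]+criteria[ \t]*:?[ \t]*$",
                text,
                re.IGNORECASE | re.MULTILINE,
            )
        ]
        seen = set()
        for _, label in headings:
            if label in seen:
                raise ValueError(f"duplicate {label.value} heading in protocol")
            seen.add(label)
        if not headings:
            sections.append(Section(SectionLabel.BODY, (0, len(text))))
        else:
            first = headings[0][0]
            if text[:first].strip():
                sections.append(Section(SectionLabel.BODY, (0, first)))
            elif first > 0:
                # leading whitespace is folded into the first section
                headings[0] = (0, headings[0][1])
            for idx, (start, label) in enumerate(headings):
                end = headings[idx + 1][0] if idx + 1 < len(headings) else len(text)
                sections.append(Section(label, (start, end)))

    return Document(
        id=doc_id,
        kind=kind,
        raw_text=text,
        sections=sections,
        sentences=split_sentences(text),
    )


def section_of(doc: Document, offset: int) -> SectionLabel:
    """Label of the section containing ``offset``.

    Raises ``ValueError`` when ``offset`` is outside ``[0, len(raw_text))``.
    """
    if not 0 <= offset < len(doc.raw_text):
        raise ValueError(f"offset {offset} out of range for document {doc.id!r}")
    for sec in doc.sections:
        if sec.span[0] <= offset < sec.span[1]:
            return sec.label
    # unreachable when sections tile the text; defensive fallback
    return SectionLabel.BODY
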