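"""Matching score, decision threshold and the explanation report.

The score is the fraction of protocol-required criteria the patient meets:
``score = n_met / n_required``.  A pair is declared a match only when the
score strictly exceeds the threshold (default 0.5 — more evidence for than
against); a protocol that requires none of the four criteria has an
undefined score and the pair is *indeterminate* rather than silently
counted either way.

Exclusion-section conflicts never move the score; they are surfaced as
flags for the human reviewer, because the score is inclusion-driven.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .criteria import CRITERION_ORDER, Criterion, CriterionResult
from .documents import Document


class Decision:
    MATCH = "match"
    NO_MATCH = "no_match"
    INDETERMINATE = "indeterminate"


@dataclass
class MatchConfig:
    threshold: float = 0.5  # strict greater-than
    criteria_enabled: frozenset[Criterion] = frozenset(CRITERION_ORDER)
    synonym_table_enabled: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must lie in [0, 1)")


def compute_score(
    results: list[CriterionResult],
) -> tuple[int, int, float | None]:
    """(n_met, n_required, score); score is None when nothing is required."""
    if len(results) > 4:
        raise ValueError("at most one result per criterion")
    n_required = sum(1 for r in results if r.required_by_protocol)
    n_met = sum(1 for r in results if r.required_by_protocol and r.satisfied)
    score = n_met / n_required if n_required else None
    return n_met, n_required, score


def decide(score: float | None, config: MatchConfig | None = None) -> str:
    config = config or MatchConfig()
    if score is None:
        return Decision.INDETERMINATE
    return Decision.MATCH if score > config.threshold else Decision.NO_MATCH


@dataclass
class MatchReport:
    patient_id: str
    protocol_id: str
    criterion_results: list[CriterionResult]
    n_required: int
    n_met: int
    score: float | None
    decision: str
    explanation: list[str] = field(default_factory=list)
    exclusion_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "protocol_id": self.protocol_id,
            "score": self.score,
            "n_met": self.n_met,
            "n_required": self.n_required,
            "decision": self.decision,
            "criteria": [
                {
                    "name": r.criterion.value,
                    "required": r.required_by_protocol,
                    "satisfied": r.satisfied,
                    "evidence": list(r.evidence_lines),
                }
                for r in self.criterion_results
            ],
            "exclusion_flags": list(self.exclusion_flags),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, **kwargs)

    def render_text(self) -> str:
        lines = [
            f"Patient {self.patient_id} vs Protocol {self.protocol_id}",
            (
                f"Matching score: {self.score:.2f} "
                f"({self.n_met} of {self.n_required} required criteria met)"
                if self.score is not None
                else "Matching score: undefined (protocol requires none of the four criteria)"
            ),
            f"Decision: {self.decision}",
        ]
        for r in self.criterion_results:
            head = f"[{r.criterion.value}]"
            if not r.required_by_protocol:
                lines.append(f"  {head} not required by protocol")
                continue
            outcome = "evidence" if r.satisfied else "no evidence"
            lines.append(f"  {head} {outcome}:")
            for ev in r.evidence_lines:
                lines.append(f"    {ev}")
        if self.exclusion_flags:
            lines.append("Exclusion-section flags:")
            for flag in self.exclusion_flags:
                lines.append(f"  {flag}")
        return "\n".join(lines)


def build_report(
    patient: Document,
    protocol: Document,
    results: list[CriterionResult],
    config: MatchConfig | None = None,
) -> MatchReport:
    """Assemble the explanation report in fixed criterion order.

    Each required criterion contributes its evidence lines to the
    explanation; exclusion conflicts are collected as flags.
    """
    config = config or MatchConfig()
    by_criterion = {r.criterion: r for r in results}
    ordered = [
        by_criterion[c]
        for c in CRITERION_ORDER
        if c in by_criterion and c in config.criteria_enabled
    ]
    n_met, n_required, score = compute_score(ordered)
    decision = decide(score, config)
    explanation = [
        line for r in ordered if r.required_by_protocol for line in r.evidence_lines
    ]
    exclusion_flags = [
        f"{r.criterion.value}: {ev}"
        for r in ordered
        if r.exclusion_conflict
        for ev in (r.exclusion_evidence or ["conflict with exclusion section"])
    ]
    return MatchReport(
        patient_id=patient.id,
        protocol_id=protocol.id,
        criterion_results=ordered,
        n_required=n_required,
        n_met=n_met,
        score=score,
        decision=decision,
        explanation=explanation,
        exclusion_flags=exclusion_flags,
    )
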