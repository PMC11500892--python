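"""Evaluation harness: confusion matrix and the four headline metrics.

Decisions are compared with gold labels per patient-protocol pair.
Indeterminate decisions (protocol required none of the criteria) are
excluded from the matrix by default and their count logged; a config flag
coerces them to no-match for a strictly binary matrix.  Percentages are
rounded half-up to two decimals so printed strings are reproducible
(14/19 -> 73.68).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

log = logging.getLogger(__name__)

MATCH = "match"
NO_MATCH = "no_match"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class MetricSet:
    """Fractions in [0, 1]; a metric with a zero denominator is None
    (absent), never reported as 0."""

    precision: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    percent: dict[str, float | None]

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "percent": dict(self.percent),
        }


def confusion(
    predictions: list[tuple[str, str]],
    gold: list[tuple[str, str]],
    indeterminate_as_no_match: bool = False,
) -> ConfusionMatrix:
    """Count TP/FN/FP/TN over identical pair-id sets.

    ``predictions`` holds (pair_id, decision) with decisions in
    {match, no_match, indeterminate}; ``gold`` holds (pair_id, label) with
    labels in {match, no_match}.  Mismatched id sets raise ``ValueError``.
    """
    pred_map = dict(predictions)
    gold_map = dict(gold)
    if len(pred_map) != len(predictions) or len(gold_map) != len(gold):
        raise ValueError("duplicate pair ids")
    if set(pred_map) != set(gold_map):
        raise ValueError("prediction and gold pair-id sets differ")

    tp = fn = fp = tn = 0
    n_indeterminate = 0
    for pair_id, label in gold_map.items():
        pred = pred_map[pair_id]
        if pred == INDETERMINATE:
            if indeterminate_as_no_match:
                pred = NO_MATCH
            else:
                n_indeterminate += 1
                continue
        if label == MATCH:
            tp += pred == MATCH
            fn += pred != MATCH
        else:
            fp += pred == MATCH
            tn += pred != MATCH
    if n_indeterminate:
        log.info("excluded %d indeterminate pair(s) from the confusion matrix",
                 n_indeterminate)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _percent(num: int, den: int) -> float | None:
    if den == 0:
        return None
    value = Decimal(num) * 100 / Decimal(den)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """precision = tp/(tp+fp), sensitivity = tp/(tp+fn),
    specificity = tn/(tn+fp), accuracy = (tp+tn)/total."""
    def frac(num: int, den: int) -> float | None:
        return num / den if den else None

    return MetricSet(
        precision=frac(cm.tp, cm.tp + cm.fp),
        sensitivity=frac(cm.tp, cm.tp + cm.fn),
        specificity=frac(cm.tn, cm.tn + cm.fp),
        accuracy=frac(cm.tp + cm.tn, cm.total),
        percent={
            "precision": _percent(cm.tp, cm.tp + cm.fp),
            "sensitivity": _percent(cm.tp, cm.tp + cm.fn),
            "specificity": _percent(cm.tn, cm.tn + cm.fp),
            "accuracy": _percent(cm.tp + cm.tn, cm.total),
        },
    )


def format_table(cm: ConfusionMatrix, ms: MetricSet) -> str:
    rows = [
        ("", "System: match", "System: no match", "Total"),
        ("Gold: match", str(cm.tp), str(cm.fn), str(cm.tp + cm.fn)),
        ("Gold: no match", str(cm.fp), str(cm.tn), str(cm.fp + cm.tn)),
        ("Total", str(cm.tp + cm.fp), str(cm.fn + cm.tn), str(cm.total)),
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    lines = ["  ".join(cell.ljust(widths[i]) for i, cell in enumerate(row)).rstrip()
             for row in rows]
    lines.append("")
    for name in ("precision", "sensitivity", "specificity", "accuracy"):
        pct = ms.percent[name]
        lines.append(f"{name}: " + (f"{pct:.2f}%" if pct is not None else "undefined"))
    return "\n".join(lines)
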