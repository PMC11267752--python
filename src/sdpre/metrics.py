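"""Micro precision/recall/F1 with the None-exclusion convention.

Relation-extraction benchmarks score only substantive relations: a
correctly predicted None contributes to no numerator and no denominator.
Incorrect predictions involving None still count — predicting a relation
where the gold is None lowers precision, and predicting None where the
gold is a relation lowers recall.  All 0/0 ratios are defined as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    n_evaluated: int
    per_class: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_evaluated": self.n_evaluated,
            "per_class": self.per_class,
        }


def micro_prf(gold: list[str], pred: list[str], none_type: str | None = "None") -> MetricsReport:
    """Micro P/R/F1 over paired label lists, ignoring correct None predictions.

    ``TP = #(pred = gold ≠ None)``, ``P = TP / #(pred ≠ None)``,
    ``R = TP / #(gold ≠ None)``; F1 is their harmonic mean (0 when both
    are 0).
    """
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    tp = sum(1 for g, p in zip(gold, pred) if g == p and g != none_type)
    pred_pos = sum(1 for p in pred if p != none_type)
    gold_pos = sum(1 for g in gold if g != none_type)
    precision = tp / pred_pos if pred_pos else 0.0
    recall = tp / gold_pos if gold_pos else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0

    per_class: dict[str, dict[str, int]] = {}
    for cls in sorted(set(gold) | set(pred)):
        per_class[cls] = {
            "tp": sum(1 for g, p in zip(gold, pred) if g == p == cls),
            "gold": sum(1 for g in gold if g == cls),
            "pred": sum(1 for p in pred if p == cls),
        }
    n_eval = len(gold) - sum(1 for g, p in zip(gold, pred) if g == p == none_type)
    return MetricsReport(precision=precision, recall=recall, f1=f1,
                         n_evaluated=n_eval, per_class=per_class)


def paired_runs_summary(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean ± population standard deviation per metric across repeated runs."""
    if not reports:
        raise ValueError("no runs to summarize")
    out = {}
    for name in ("precision", "recall", "f1"):
        vals = np.array([getattr(r, name) for r in reports])
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return out


def class_distribution(labels: list[str]) -> dict[str, int]:
    """Class-count vector, used by the imputation-bias report."""
    return dict(Counter(labels))
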