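"""Overlap metrics: Dice, IoU, precision and recall per class.

Per class ``c`` with prediction set ``P`` and truth set ``T`` (pixels equal
to ``c``): ``Dice = 2|P∧T| / (|P|+|T|)``, ``IoU = |P∩T| / |P∪T|``,
``Pre = |P∩T| / |P|``, ``Rec = |P∩T| / |T|``.  Dice is the F-score (harmonic
mean of precision and recall) and relates to IoU by
``Dice = 2 IoU / (1 + IoU)``.

Empty-class conventions (both sets empty → 1, exactly one empty → 0) follow
common challenge scoring and are recorded in each metrics record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ClassMetrics", "MetricsRecord", "evaluate", "write_metrics_csv"]

EMPTY_CONVENTION = "empty-vs-empty=1; empty-vs-nonempty=0"


@dataclass(frozen=True)
class ClassMetrics:
    dice: float
    iou: float
    precision: float
    recall: float
    pred_size: int
    truth_size: int


@dataclass(frozen=True)
class MetricsRecord:
    """Per-class metrics plus macro averages (background excluded by default)."""

    per_class: dict[int, ClassMetrics]
    macro_dice: float
    macro_iou: float
    macro_precision: float
    macro_recall: float
    include_background: bool = False
    convention: str = field(default=EMPTY_CONVENTION)


def _ratio(num: int, den: int, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def evaluate(pred, truth, K: int, include_background: bool = False) -> MetricsRecord:
    """Compute overlap metrics of two integer label masks with labels in [0, K)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    for name, m in (("pred", pred), ("truth", truth)):
        if m.size and (m.min() < 0 or m.max() >= K):
            raise ValueError(f"{name} labels outside [0, {K})")

    per_class: dict[int, ClassMetrics] = {}
    for c in range(K):
        p = pred == c
        t = truth == c
        inter = int(np.sum(p & t))
        np_, nt = int(p.sum()), int(t.sum())
        union = np_ + nt - inter
        both_empty = np_ == 0 and nt == 0
        per_class[c] = ClassMetrics(
            dice=_ratio(2 * inter, np_ + nt, both_empty),
            iou=_ratio(inter, union, both_empty),
            precision=_ratio(inter, np_, both_empty),
            recall=_ratio(inter, nt, both_empty),
            pred_size=np_,
            truth_size=nt,
        )

    first = 0 if include_background else 1
    sel = [per_class[c] for c in range(first, K)]
    return MetricsRecord(
        per_class=per_class,
        macro_dice=float(np.mean([m.dice for m in sel])),
        macro_iou=float(np.mean([m.iou for m in sel])),
        macro_precision=float(np.mean([m.precision for m in sel])),
        macro_recall=float(np.mean([m.recall for m in sel])),
        include_background=include_background,
    )


CSV_COLUMNS = [
    "case",
    "class",
    "dice",
    "iou",
    "precision",
    "recall",
    "pred_size",
    "truth_size",
]


def write_metrics_csv(records: dict[str, MetricsRecord], path) -> None:
    """One row per (case, class) plus a macro row per case."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for case, rec in records.items():
            for c, m in rec.per_class.items():
                writer.writerow(
                    [case, c, m.dice, m.iou, m.precision, m.recall, m.pred_size, m.truth_size]
                )
            writer.writerow(
                [case, "macro", rec.macro_dice, rec.macro_iou, rec.macro_precision, rec.macro_recall, "", ""]
            )
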