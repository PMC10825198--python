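"""Class-support-weighted binary classification metrics.

Each task designates a positive class (left, extra-temporal, posterior) for
the confusion-matrix orientation.  Every reported metric except accuracy is
*weighted*: the per-class value (treating that class as positive) averaged
over both classes with weights proportional to the class support in the true
labels, so a class absent from a fold contributes zero weight.  A ratio with
zero denominator contributes 0 and is flagged.
"""

from __future__ import annotations

from typing import Hashable, Sequence

METRICS = ("accuracy", "precision_w", "npv_w", "specificity_w", "f1_w")


def confusion_counts(
    y_true: Sequence[Hashable],
    y_pred: Sequence[Hashable],
    positive_class: Hashable,
) -> dict[str, int]:
    """2x2 confusion counts with the designated positive class."""
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive_class:
            if t == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_class:
                fn += 1
            else:
                tn += 1
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_weighted_metrics(
    y_true: Sequence[Hashable],
    y_pred: Sequence[Hashable],
    positive_class: Hashable,
    negative_class: Hashable,
) -> tuple[dict[str, float], dict[str, int], list[str]]:
    """Weighted accuracy/precision/NPV/specificity/F1 plus confusion counts.

    Returns ``(metrics, confusion, flags)`` where ``flags`` names any
    zero-denominator ratio that contributed 0.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("label lists must be equal-length and non-empty")
    pair = {positive_class, negative_class}
    for label in list(y_true) + list(y_pred):
        if label not in pair:
            raise ValueError(f"label {label!r} outside the task pair {pair}")

    n = len(y_true)
    confusion = confusion_counts(y_true, y_pred, positive_class)
    flags: list[str] = []
    metrics = {"accuracy": (confusion["TP"] + confusion["TN"]) / n}

    weighted = {"precision_w": 0.0, "npv_w": 0.0, "specificity_w": 0.0, "f1_w": 0.0}
    for cls in (positive_class, negative_class):
        support = sum(1 for t in y_true if t == cls)
        if support == 0:
            continue
        weight = support / n
        c = confusion_counts(y_true, y_pred, cls)
        precision = _safe_div(c["TP"], c["TP"] + c["FP"], flags, f"precision[{cls}]")
        recall = _safe_div(c["TP"], c["TP"] + c["FN"], flags, f"recall[{cls}]")
        weighted["precision_w"] += weight * precision
        weighted["npv_w"] += weight * _safe_div(
            c["TN"], c["TN"] + c["FN"], flags, f"npv[{cls}]"
        )
        weighted["specificity_w"] += weight * _safe_div(
            c["TN"], c["TN"] + c["FP"], flags, f"specificity[{cls}]"
        )
        weighted["f1_w"] += weight * _safe_div(
            2 * precision * recall, precision + recall, flags, f"f1[{cls}]"
        )
    metrics.update(weighted)
    return metrics, confusion, flags
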