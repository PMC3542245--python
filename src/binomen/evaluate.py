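"""Scoring of predicted names against gold annotations.

The default evaluation unit is the unique name surface (list-vs-list set
comparison, whitespace-normalized, case-sensitive); an exact mention-span
mode is available for stricter NER-style scoring.  Precision is the
fraction of retrieved names that are correct, recall the fraction of gold
names retrieved, F their harmonic mean (0 when undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

from binomen.textio import GoldAnnotation


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


def precision_recall_f(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = tp/(tp+fp), R = tp/(tp+fn), F = harmonic mean; each defined as 0
    when its denominator is 0.  Computed at full float precision."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _normalize(surface: str) -> str:
    return " ".join(surface.split())


def match_names(gold: GoldAnnotation, predicted, mode: str = "unique_name") -> EvalResult:
    """Count TP/FP/FN between gold and predictions.

    ``predicted`` may be mention objects (with ``surface``/``start``/``end``)
    or plain strings (unique_name mode only).
    """
    if mode == "unique_name":
        gold_set = {_normalize(s) for s in gold.names}
        pred_set = set()
        for p in predicted:
            pred_set.add(_normalize(p if isinstance(p, str) else p.surface))
        tp = len(gold_set & pred_set)
        fp = len(pred_set - gold_set)
        fn = len(gold_set - pred_set)
    elif mode == "mention_span":
        if gold.mentions is None:
            raise ValueError("mention_span mode requires gold annotations with spans")
        gold_spans = set(gold.mentions)
        pred_spans = {(p.start, p.end) for p in predicted}
        tp = len(gold_spans & pred_spans)
        fp = len(pred_spans - gold_spans)
        fn = len(gold_spans - pred_spans)
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    precision, recall, f = precision_recall_f(tp, fp, fn)
    return EvalResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f_score=f)
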