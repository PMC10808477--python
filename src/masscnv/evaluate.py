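"""Diagnostic evaluation: confusion matrices, sensitivity/specificity,
predictive values and prevalence.

Evaluation is sample-level by default (a sample is *positive* when it
carries at least one CNV event); a fragment-level mode simply evaluates
(sample, fragment) keys instead. Percentages are kept at full precision
internally and rounded half-up to one decimal for display, so 281/285 =
98.596% displays as 98.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .errors import MasscnvError
from .events import STATUS_POSITIVE


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (282.5 -> 282.5 stays exact in Decimal),
    matching clinical-report rounding rather than banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The confusion matrix after exchanging the positive/negative labels."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percent metrics at full precision; ``None`` marks an undefined value
    (zero denominator), which is deliberately distinct from 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def display(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else round_half_up(v, 1))
            for k, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def confusion(calls: Mapping[str, str], truth: Mapping[str, str]) -> ConfusionMatrix:
    """Count TP/FP/TN/FN between called and true status maps.

    Keys may be sample ids (sample-level) or (sample, fragment) pairs
    (fragment-level); the two maps must cover identical key sets. A status
    is positive iff it equals ``"cnv_positive"``.
    """
    call_keys, truth_keys = set(calls), set(truth)
    if call_keys != truth_keys:
        only_calls = sorted(map(str, call_keys - truth_keys))[:10]
        only_truth = sorted(map(str, truth_keys - call_keys))[:10]
        raise MasscnvError(
            f"sample sets differ: only in calls {only_calls}, only in truth {only_truth}"
        )
    tp = fp = tn = fn = 0
    for key in calls:
        called = calls[key] == STATUS_POSITIVE
        actual = truth[key] == STATUS_POSITIVE
        if called and actual:
            tp += 1
        elif called and not actual:
            fp += 1
        elif not called and actual:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV in percent (full precision)."""

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=pct(cm.tp, cm.tp + cm.fn),
        specificity=pct(cm.tn, cm.tn + cm.fp),
        ppv=pct(cm.tp, cm.tp + cm.fp),
        npv=pct(cm.tn, cm.tn + cm.fn),
    )


def prevalence(positives: int, total: int, ndigits: int | None = 1) -> float:
    """Percent of positives in a cohort; display-rounded by default."""
    if total <= 0:
        raise MasscnvError("prevalence requires a positive total")
    value = 100.0 * positives / total
    return value if ndigits is None else round_half_up(value, ndigits)
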