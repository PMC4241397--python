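"""Classification performance and inter-rater reliability statistics.

Conventions: the *patient* group is the positive class and
``further_evaluation`` the positive prediction, so sensitivity is the
referral rate among patients and specificity the watchful-waiting rate
among controls.  The correct classification rate (CCR) is overall
accuracy, (TP+TN)/N.

Cohen's kappa is the chance-corrected agreement between two raters,
kappa = (po - pe) / (1 - pe), used here for the reliability of the
clock-drawing criteria between examiners.  When both raters are
constant and identical (pe = 1) kappa is undefined and flagged rather
than imputed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .instrument import Decision, InputError

__all__ = [
    "CONTROL",
    "PATIENT",
    "ConfusionCounts",
    "ClassificationMetrics",
    "KappaResult",
    "classification_metrics",
    "cohens_kappa",
    "format_percent",
]

CONTROL = "control"
PATIENT = "patient"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts (patient positive, referral positive)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise InputError("confusion counts must describe at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    """Sensitivity / specificity / CCR with undefined metrics flagged.

    A metric is ``None`` when its reference class is absent (e.g. no
    patients in the sample leaves sensitivity undefined); ``undefined``
    lists the names of such metrics.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ccr: float
    counts: ConfusionCounts

    @property
    def undefined(self) -> tuple[str, ...]:
        out = []
        if self.sensitivity is None:
            out.append("sensitivity")
        if self.specificity is None:
            out.append("specificity")
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ccr": self.ccr,
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "undefined": list(self.undefined),
        }

    def format(self) -> str:
        """Percent-formatted one-line summary (one decimal place)."""
        parts = [
            f"sensitivity = {format_percent(self.sensitivity)}",
            f"specificity = {format_percent(self.specificity)}",
            f"CCR = {format_percent(self.ccr)}",
        ]
        return ", ".join(parts)


def format_percent(x: Optional[float]) -> str:
    return "undefined" if x is None else f"{100.0 * x:.1f}%"


def confusion_counts(
    predictions: Sequence[Decision], gold: Sequence[str]
) -> ConfusionCounts:
    if len(predictions) != len(gold):
        raise InputError(
            f"predictions ({len(predictions)}) and gold labels ({len(gold)}) "
            "must have equal length"
        )
    tp = fn = tn = fp = 0
    for pred, label in zip(predictions, gold):
        if label not in (CONTROL, PATIENT):
            raise InputError(f"gold label must be 'control' or 'patient', got {label!r}")
        positive = pred is Decision.FURTHER_EVALUATION or pred == Decision.FURTHER_EVALUATION
        if label == PATIENT:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def classification_metrics(
    predictions: Sequence[Decision], gold: Sequence[str]
) -> ClassificationMetrics:
    """Sensitivity, specificity and CCR of predicted decisions vs gold labels."""
    c = confusion_counts(predictions, gold)
    sens = c.tp / c.n_positive if c.n_positive else None
    spec = c.tn / c.n_negative if c.n_negative else None
    ccr = (c.tp + c.tn) / c.total
    return ClassificationMetrics(sensitivity=sens, specificity=spec, ccr=ccr, counts=c)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its observed and chance-expected agreement.

    ``kappa`` is ``None`` (flagged via ``undefined``) when the expected
    agreement is 1, i.e. both raters used a single identical category.
    """

    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float

    @property
    def undefined(self) -> bool:
        return self.kappa is None

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "undefined": self.undefined,
        }


def cohens_kappa(rater_a: Sequence, rater_b: Sequence) -> KappaResult:
    """Cohen's kappa between two raters over a shared category space."""
    if len(rater_a) != len(rater_b):
        raise InputError("raters must score the same cases (equal lengths)")
    n = len(rater_a)
    if n < 2:
        raise InputError("kappa requires at least two rated cases")
    po = sum(a == b for a, b in zip(rater_a, rater_b)) / n
    counts_a = Counter(rater_a)
    counts_b = Counter(rater_b)
    categories = set(counts_a) | set(counts_b)
    pe = sum(counts_a[c] * counts_b[c] for c in categories) / (n * n)
    if pe >= 1.0:
        return KappaResult(kappa=None, observed_agreement=po, expected_agreement=pe)
    return KappaResult(
        kappa=(po - pe) / (1.0 - pe),
        observed_agreement=po,
        expected_agreement=pe,
    )
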