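"""Rank tests, exact contingency tests, confusion metrics, ROC/AUC, and
ingestion conventions for third-party predictor scores.

Conventions used throughout the package:

* ``MUT`` is the positive class in every confusion matrix and ROC.
* Mann-Whitney p-values are two-sided; the exact null distribution is used
  when both groups have at most 12 observations and the pooled sample is
  tie-free, otherwise the normal approximation with tie and continuity
  corrections.  The returned U is the smaller of the two group statistics.
* Fisher's exact test is two-sided, summing hypergeometric probabilities
  no larger than that of the observed table.
* Metric arithmetic is exact (rational) before the final float conversion;
  a metric whose denominator is zero is reported as ``None``, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import IngestionError, InvalidInputError
from .variants import MUT, SNP


# ---------------------------------------------------------------------------
# Rank and exact tests
# ---------------------------------------------------------------------------

def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    two_sided: bool = True,
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test between two independent samples.

    Parameters
    ----------
    group_a, group_b
        Non-empty samples.
    two_sided
        Two-sided by default; ``False`` tests ``group_a`` stochastically
        greater than ``group_b``.
    method
        ``"auto"`` (exact when both groups <= 12 and tie-free, otherwise
        normal approximation with tie and continuity corrections),
        ``"exact"`` or ``"asymptotic"``.

    Returns
    -------
    (U, p)
        ``U`` is min(U_a, U_b); ``p`` per the chosen method.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (tie_free and max(a.size, b.size) <= 12) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise InvalidInputError(f"unknown method {method!r}")
    alternative = "two-sided" if two_sided else "greater"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    u_a = float(res.statistic)
    u_min = min(u_a, a.size * b.size - u_a)
    return u_min, float(res.pvalue)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative counts.

    A table with a zero margin carries no information about association;
    p = 1.0 is returned with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InvalidInputError("need a 2x2 table of non-negative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("2x2 table has a zero margin; Fisher p set to 1.0",
                      stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with MUT as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("counts must be non-negative")
        if self.total == 0:
            raise InvalidInputError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls, true_labels: Sequence[str], predicted_labels: Sequence[str]
    ) -> "ConfusionCounts":
        if len(true_labels) != len(predicted_labels):
            raise InvalidInputError("label vectors differ in length")
        tp = tn = fp = fn = 0
        for truth, pred in zip(true_labels, predicted_labels):
            if truth == MUT and pred == MUT:
                tp += 1
            elif truth == SNP and pred == SNP:
                tn += 1
            elif truth == SNP and pred == MUT:
                fp += 1
            elif truth == MUT and pred == SNP:
                fn += 1
            else:
                raise InvalidInputError(f"labels must be SNP/MUT, got {truth}/{pred}")
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class EvaluationReport:
    """Binary-classification metrics; ``None`` marks an undefined metric."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    auc: float | None = None
    fisher_p: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "auc": self.auc,
            "fisher_p": self.fisher_p,
        }


def _ratio(num: int, den: int) -> float | None:
    return float(Fraction(num, den)) if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Accuracy, precision, sensitivity, specificity and NPV from counts.

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    NPV         = TN / (TN + FN)
    """
    c = counts
    return EvaluationReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, float]:
    """ROC curve points and rank-based AUC, MUT as positive class.

    AUC is the Mann-Whitney estimator with ties counted 1/2, identical to
    trapezoidal integration of the curve over all distinct score
    thresholds.  Returns ``(points, auc)`` where ``points`` is an array of
    (FPR, TPR) pairs from (0, 0) to (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == MUT else 0 for l in labels])
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("ROC needs both classes present")
    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = distinct + 1 - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


# ---------------------------------------------------------------------------
# Third-party predictor score conventions
# ---------------------------------------------------------------------------

def transform_sift_score(score: float) -> float:
    """Reorient an original SIFT score so that higher means mutation.

    SIFT natively assigns low scores to damaging substitutions; the
    comparable scale used here is ``1 - score``.
    """
    if not 0.0 <= score <= 1.0:
        raise IngestionError(f"SIFT score {score} outside [0, 1]")
    return 1.0 - score


def binarize_external(score: float, tool: str) -> str:
    """Binary SNP/MUT call from a third-party predictor's original score.

    SIFT: original score < 0.05 -> MUT (strict inequality; 0.05 is SNP).
    PolyPhen-2: probabilistic score >= 0.5 -> MUT (boundary inclusive).
    """
    if not 0.0 <= score <= 1.0:
        raise IngestionError(f"{tool} score {score} outside [0, 1]")
    t = tool.strip().lower().replace("-", "")
    if t == "sift":
        return MUT if score < 0.05 else SNP
    if t in ("polyphen2", "polyphen"):
        return MUT if score >= 0.5 else SNP
    raise IngestionError(f"unknown tool {tool!r} (expected sift or polyphen2)")


def evaluate_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    scores: Sequence[float] | None = None,
) -> EvaluationReport:
    """Full evaluation: confusion metrics, Fisher p of the predicted-vs-true
    crosstab, and (if continuous scores are given) rank-based AUC."""
    counts = ConfusionCounts.from_labels(true_labels, predicted_labels)
    report = confusion_metrics(counts)
    fisher_p = fisher_exact([[counts.tp, counts.fn], [counts.fp, counts.tn]])
    auc = None
    if scores is not None:
        _, auc = roc_auc(scores, true_labels)
    return EvaluationReport(
        accuracy=report.accuracy,
        precision=report.precision,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        npv=report.npv,
        auc=auc,
        fisher_p=fisher_p,
    )
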