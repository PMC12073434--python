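"""Evaluation framework: confusion counts, accuracy/F1 with CIs, paired tests.

Compound-ingredient identification is scored per meal plan against ground
truth labels: a true compound predicted as compound is a true positive, a
basic ingredient predicted as compound a false positive, and so on.  Per-plan
accuracy and F1 feed a t-distribution confidence interval on the mean, and
pairwise model comparisons are gated on normality: a Shapiro–Wilk test on the
paired differences routes to a paired t-test when normality is not rejected
and to a Wilcoxon signed-rank test otherwise, at α = 0.05 throughout.

Zero-denominator conventions keep per-plan scores defined on plans with no
compound ingredients; each application of a convention is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .meal_plans import normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthLabels",
    "ConfusionCounts",
    "EvaluationMetrics",
    "PairedComparison",
    "confusion",
    "metrics_from_confusion",
    "mean_ci",
    "paired_compare",
    "pool_evaluators",
    "anova_oneway",
    "holm_adjust",
]

COMPOUND = "compound"
BASIC = "basic"


@dataclass(frozen=True)
class GroundTruthLabels:
    """One evaluator's compound/basic labels for one plan's ingredients."""

    evaluator_id: str
    plan_id: str
    labels: Mapping[str, str]  # normalized ingredient name -> compound|basic

    def __post_init__(self) -> None:
        for name, label in self.labels.items():
            if label not in (COMPOUND, BASIC):
                raise ValueError(f"label for {name!r} must be 'compound' or 'basic', got {label!r}")

    @classmethod
    def from_names(
        cls, evaluator_id: str, plan_id: str, compounds: Iterable[str], basics: Iterable[str]
    ) -> "GroundTruthLabels":
        labels = {normalize_name(n): COMPOUND for n in compounds}
        for n in basics:
            key = normalize_name(n)
            if key in labels:
                raise ValueError(f"ingredient {n!r} labeled both compound and basic")
            labels[key] = BASIC
        return cls(evaluator_id=evaluator_id, plan_id=plan_id, labels=labels)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class EvaluationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class PairedComparison:
    test_kind: str  # paired_t | wilcoxon | degenerate
    statistic: float
    p_value: float
    normality_p: float | None
    alpha: float = 0.05
    n: int = 0


def confusion(truth: GroundTruthLabels, predicted_compounds: Iterable[str]) -> ConfusionCounts:
    """Confusion counts of predicted compound names against one plan's truth.

    Predicted names are normalized before matching.  A predicted name that
    resolves to no plan ingredient is a hallucination and counts as a false
    positive (with a warning) — silently dropping it would inflate precision.
    """
    predicted = {normalize_name(p) for p in predicted_compounds}
    tp = fp = fn = tn = 0
    for name, label in truth.labels.items():
        hit = name in predicted
        if label == COMPOUND:
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    unmatched = predicted - set(truth.labels)
    if unmatched:
        logger.warning(
            "plan %s: %d predicted name(s) not in plan, counted as false positives: %s",
            truth.plan_id,
            len(unmatched),
            sorted(unmatched),
        )
        fp += len(unmatched)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_confusion(c: ConfusionCounts) -> EvaluationMetrics:
    """Per-plan accuracy, precision, recall and F1 from confusion counts.

    Conventions for empty denominators (logged when applied):
    no predictions (tp+fp = 0): precision 1 if also nothing to find (fn = 0)
    else 0; no true compounds (tp+fn = 0): recall 1 if also nothing claimed
    (fp = 0) else 0.  F1 is the harmonic mean of the resulting pair, 0 when
    both are 0.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        precision = 1.0 if c.fn == 0 else 0.0
        logger.debug("precision convention applied (no predictions): %s", precision)
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall = 1.0 if c.fp == 0 else 0.0
        logger.debug("recall convention applied (no true compounds): %s", recall)
    else:
        recall = c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvaluationMetrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """t-distribution confidence interval for the mean of per-plan scores.

    Returns (mean, ci_low, ci_high).  With identical values the interval has
    zero width.  Requires at least two values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for a confidence interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = float(arr.mean())
    if np.ptp(arr) == 0.0:  # identical values: zero-width interval
        return mean, mean, mean
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    tcrit = float(sps.t.ppf(0.5 + level / 2, df=arr.size - 1))
    return mean, mean - tcrit * sem, mean + tcrit * sem


def paired_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], alpha: float = 0.05
) -> PairedComparison:
    """Normality-gated paired comparison of two aligned per-plan score series.

    Shapiro–Wilk runs on the differences a − b: when normality is not rejected
    at *alpha* the comparison is a paired t-test (statistic t, df n−1),
    otherwise a Wilcoxon signed-rank test (statistic V); p-values two-sided.
    All-zero differences are a degenerate comparison (p = 1, no test run),
    since normality testing on a constant is undefined; constant non-zero
    differences also route to Wilcoxon for the same reason.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score series must be aligned and of equal length")
    if a.size < 3:
        raise ValueError("need at least three pairs")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedComparison(test_kind="degenerate", statistic=0.0, p_value=1.0, normality_p=None, alpha=alpha, n=a.size)
    if np.ptp(diffs) == 0:
        normality_p = None  # Shapiro-Wilk undefined on a constant sample
        normal = False
    else:
        normality_p = float(sps.shapiro(diffs).pvalue)
        normal = normality_p > alpha
    if normal:
        res = sps.ttest_rel(a, b)
        return PairedComparison(
            test_kind="paired_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p=normality_p,
            alpha=alpha,
            n=a.size,
        )
    res = sps.wilcoxon(a, b)
    return PairedComparison(
        test_kind="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=normality_p,
        alpha=alpha,
        n=a.size,
    )


def pool_evaluators(per_evaluator_scores: Mapping[str, Sequence[float]]) -> list[float]:
    """Concatenate per-plan scores across evaluators (same plans, same order).

    Three evaluators of 15 plans each pool to 45 plan-level scores, on which
    :func:`paired_compare` then operates pairwise between models.
    """
    lengths = {len(v) for v in per_evaluator_scores.values()}
    if len(lengths) > 1:
        raise ValueError(f"evaluators cover different numbers of plans: {sorted(lengths)}")
    pooled: list[float] = []
    for evaluator_id in sorted(per_evaluator_scores):
        pooled.extend(float(v) for v in per_evaluator_scores[evaluator_id])
    return pooled


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA over two or more groups; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two values")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, available behind a flag for users who want
    family-wise control; the default reporting applies none."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
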