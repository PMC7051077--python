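"""Screening decision analysis for SCB against TSB.

Confusion matrices at SCB cut-offs versus TSB thresholds, the standard
screening metrics with exact (Clopper-Pearson) confidence intervals, ROC
curves with trapezoidal AUC, Youden-optimal cut-off selection, and
Bland-Altman agreement statistics.

Positivity convention: the condition is ``TSB > tsb_threshold`` and the
test is ``SCB > scb_cutoff`` -- strict inequalities, ties negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ProportionCI",
    "ScreeningMetrics",
    "ROCCurve",
    "BlandAltmanStats",
    "confusion_at",
    "clopper_pearson",
    "metrics_from_confusion",
    "roc_curve",
    "youden_optimal",
    "bland_altman",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


class ProportionCI(NamedTuple):
    """A proportion with its 95% confidence interval."""

    point: float
    lo: float
    hi: float


@dataclass(frozen=True)
class ScreeningMetrics:
    """Sensitivity, specificity, PPV and NPV with 95% CIs.

    A metric whose denominator is zero is undefined and reported as None
    rather than silently coerced to 0.
    """

    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]

    def to_dict(self) -> dict:
        def conv(m: Optional[ProportionCI]):
            return None if m is None else {"point": m.point, "ci95": [m.lo, m.hi]}

        return {
            "sensitivity": conv(self.sensitivity),
            "specificity": conv(self.specificity),
            "ppv": conv(self.ppv),
            "npv": conv(self.npv),
        }


@dataclass(frozen=True)
class ROCCurve:
    """ROC sweep over observed SCB cut-offs (plus +/-inf sentinels)."""

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class BlandAltmanStats:
    """Mean difference (bias) and 1.96-SD limits of agreement, umol/L."""

    bias: float
    loa_low: float
    loa_high: float


def _check_paired(scb, tsb):
    scb = np.asarray(scb, dtype=float)
    tsb = np.asarray(tsb, dtype=float)
    if scb.shape != tsb.shape or scb.ndim != 1 or scb.size < 1:
        raise ValueError("scb and tsb must be equal-length non-empty 1-D sequences")
    return scb, tsb


def confusion_at(
    scb: Sequence[float],
    tsb: Sequence[float],
    scb_cutoff: float,
    tsb_threshold: float,
) -> ConfusionCounts:
    """Tally the confusion matrix for test SCB > cutoff vs condition
    TSB > threshold."""
    scb, tsb = _check_paired(scb, tsb)
    cond = tsb > tsb_threshold
    test = scb > scb_cutoff
    return ConfusionCounts(
        tp=int(np.sum(cond & test)),
        fn=int(np.sum(cond & ~test)),
        tn=int(np.sum(~cond & ~test)),
        fp=int(np.sum(~cond & test)),
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Exact binomial confidence interval for k successes out of n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("require 0 <= k <= n, n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k / n, lo, hi)


def metrics_from_confusion(c: ConfusionCounts) -> ScreeningMetrics:
    """Screening metrics with exact 95% CIs from a confusion matrix."""

    def ratio(k: int, n: int) -> Optional[ProportionCI]:
        return None if n == 0 else clopper_pearson(k, n)

    return ScreeningMetrics(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        ppv=ratio(c.tp, c.tp + c.fp),
        npv=ratio(c.tn, c.tn + c.fn),
    )


def roc_curve(
    scb: Sequence[float],
    tsb: Sequence[float],
    tsb_threshold: float,
) -> ROCCurve:
    """ROC curve of SCB as a screen for TSB > threshold.

    Cut-offs sweep the observed SCB values plus +/-inf sentinels (no
    interpolation); AUC is the trapezoidal area over (FPR, TPR), which
    for a step ROC equals the Mann-Whitney two-sample statistic
    U / (n+ * n-) with ties counted half.
    """
    scb, tsb = _check_paired(scb, tsb)
    cond = tsb > tsb_threshold
    n_pos = int(np.sum(cond))
    n_neg = int(np.sum(~cond))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both condition classes must be non-empty for a ROC curve")
    cutoffs = np.concatenate(([-np.inf], np.unique(scb), [np.inf]))
    tpr = np.empty_like(cutoffs)
    fpr = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        test = scb > c
        tpr[i] = np.sum(test & cond) / n_pos
        fpr[i] = np.sum(test & ~cond) / n_neg
    # Sorted by ascending cutoff, tpr/fpr descend from (1,1) to (0,0).
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCCurve(cutoffs=cutoffs, tpr=tpr, fpr=fpr, auc=auc)


def youden_optimal(roc: ROCCurve) -> float:
    """Cut-off maximizing Youden's J = TPR - FPR.

    Ties break toward the lower cut-off, i.e. toward higher sensitivity --
    the safe direction for a screening tool where a false negative is the
    costly error.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    # cutoffs are ascending, so the first maximizer is the lowest cutoff
    return float(roc.cutoffs[best[0]])


def bland_altman(scb: Sequence[float], tsb: Sequence[float]) -> BlandAltmanStats:
    """Bland-Altman agreement: bias and limits of agreement of SCB - TSB."""
    scb, tsb = _check_paired(scb, tsb)
    if scb.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = scb - tsb
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanStats(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)
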