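"""ROC analysis: empirical curves, DeLong AUC variance, Youden-optimal
operating points, and exact binomial confidence intervals for Se/Sp.

The AUC is the Mann-Whitney probability that a random positive scores
past a random negative; its standard error comes from the DeLong
placement-value decomposition.  Orientation is chosen so AUC >= 0.5 and
is reported with the criterion (e.g. ``>0.42`` when high scores predict
the positive class, ``<=16.73`` when low values do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "ROCResult",
    "TwoByTwo",
    "roc_with_delong",
    "youden_optimal",
    "clopper_pearson_ci",
    "binary_test_performance",
    "BinaryTestResult",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion counts of a binary test against the class truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise InputError("both classes must be represented")


@dataclass
class ROCResult:
    """Empirical ROC with DeLong variance and the Youden-optimal point."""

    thresholds: np.ndarray  # candidate criteria (observed score values)
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    se_delong: float
    ci_low: float
    ci_high: float
    direction: str  # '>' high scores predict positives; '<=' low scores do
    criterion: float  # Youden-optimal cut, at an observed score value
    youden_j: float
    se_opt: float
    sp_opt: float
    se_ci: tuple
    sp_ci: tuple
    n_pos: int
    n_neg: int

    @property
    def criterion_text(self) -> str:
        return f"{self.direction}{self.criterion:g}"

    def classify(self, scores) -> np.ndarray:
        """Apply the optimal criterion to scores; 1 = predicted positive."""
        s = np.asarray(scores, dtype=float)
        return (s > self.criterion) if self.direction == ">" else (s <= self.criterion)


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) two-sided binomial confidence interval for k/n."""
    if not 0 <= k <= n or n < 1:
        raise InputError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the empirical AUC from placement values."""
    n1, n0 = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.empty(n1)
    v01 = np.empty(n0)
    for i, s in enumerate(pos):
        v10[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / n0
    for j, s in enumerate(neg):
        v01[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(np.sqrt(s10 / n1 + s01 / n0))


def roc_with_delong(scores, labels, level: float = 0.95) -> ROCResult:
    """Empirical ROC of continuous scores against 0/1 labels.

    The curve is evaluated at every distinct observed score; the AUC uses
    the Mann-Whitney identity; the optimal criterion maximizes the Youden
    index J = Se + Sp - 1 (ties resolved toward higher specificity), and
    Se/Sp at the optimum carry exact binomial CIs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be present for ROC analysis")

    # Mann-Whitney AUC for the '>' orientation
    gt = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc_gt = gt / (pos.size * neg.size)
    direction = ">" if auc_gt >= 0.5 else "<="
    auc = auc_gt if direction == ">" else 1.0 - auc_gt

    se = _delong_se(pos, neg)
    z = sps.norm.ppf(0.5 + level / 2)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)

    thresholds = np.unique(scores)
    if direction == ">":
        sens = np.array([(pos > t).mean() for t in thresholds])
        spec = np.array([(neg <= t).mean() for t in thresholds])
    else:
        sens = np.array([(pos <= t).mean() for t in thresholds])
        spec = np.array([(neg > t).mean() for t in thresholds])

    j = sens + spec - 1.0
    # maximal J; among ties prefer higher specificity, then lower threshold
    order = sorted(
        range(thresholds.size), key=lambda i: (-j[i], -spec[i], thresholds[i])
    )
    best = order[0]
    k_se = int(round(sens[best] * pos.size))
    k_sp = int(round(spec[best] * neg.size))
    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        se_delong=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        direction=direction,
        criterion=float(thresholds[best]),
        youden_j=float(j[best]),
        se_opt=float(sens[best]),
        sp_opt=float(spec[best]),
        se_ci=clopper_pearson_ci(k_se, pos.size, level),
        sp_ci=clopper_pearson_ci(k_sp, neg.size, level),
        n_pos=pos.size,
        n_neg=neg.size,
    )


def youden_optimal(roc: ROCResult) -> tuple[str, float, float, float]:
    """The Youden-optimal operating point of a fitted ROC:
    ``(criterion_text, J, Se, Sp)``."""
    return roc.criterion_text, roc.youden_j, roc.se_opt, roc.sp_opt


@dataclass(frozen=True)
class BinaryTestResult:
    se: float
    sp: float
    auc: float
    youden_j: float
    se_ci: tuple
    sp_ci: tuple


def binary_test_performance(counts: TwoByTwo, level: float = 0.95) -> BinaryTestResult:
    """Se/Sp/AUC/J of a single-threshold (binary) test from its confusion
    counts, with exact binomial CIs.  For a binary predictor the
    trapezoidal AUC is (Se + Sp) / 2."""
    se = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    return BinaryTestResult(
        se=se,
        sp=sp,
        auc=(se + sp) / 2.0,
        youden_j=se + sp - 1.0,
        se_ci=clopper_pearson_ci(counts.tp, counts.tp + counts.fn, level),
        sp_ci=clopper_pearson_ci(counts.tn, counts.tn + counts.fp, level),
    )
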