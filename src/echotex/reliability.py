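"""Intra-reader reproducibility: two-way absolute-agreement ICC.

Two extraction sessions of the same lesions are compared per feature with
the intraclass correlation coefficient from the two-way ANOVA
decomposition (random subjects x random sessions, absolute agreement).
The average-measures form ICC(A,k) is the default, with the F-based 95%
confidence interval; features below the reproducibility threshold
(default 0.85) are excluded from further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedICCError
from .tables import FeatureTable

__all__ = ["ICCResult", "icc_agreement", "filter_reproducible"]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_measurements: int


def icc_agreement(m1, m2, average: bool = True, level: float = 0.95) -> ICCResult:
    """Absolute-agreement ICC between two measurement sessions.

    ``average=True`` gives the average-of-2 form ICC(A,k); ``False`` the
    single-measure form ICC(A,1).  The confidence interval follows the
    standard Satterthwaite-approximated F construction; the average-
    measures interval is the single-measures interval stepped up by
    Spearman-Brown.

    Raises :class:`UndefinedICCError` when there is no between-subject
    variance to agree about.
    """
    y = np.column_stack([np.asarray(m1, dtype=float), np.asarray(m2, dtype=float)])
    n, k = y.shape
    if n < 3:
        raise InputError("at least 3 subjects required for an ICC")
    if not np.all(np.isfinite(y)):
        raise InputError("ICC inputs must be finite")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        raise UndefinedICCError("zero between-subject variance")

    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icck = (msr - mse) / (msr + (msc - mse) / n)

    # F-based CI for ICC(A,1) (McGraw & Wong case 2A), Spearman-Brown for k
    alpha = 1.0 - level
    if icc1 < 1.0 and mse > 0:
        a = k * icc1 / (n * (1.0 - icc1))
        b = 1.0 + k * icc1 * (n - 1) / (n * (1.0 - icc1))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_up = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_lo = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_up * mse) / (
            f_up * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_lo * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lo * msr
        )
    else:  # perfect agreement: degenerate interval
        lo1 = hi1 = 1.0

    def _sb(r):  # Spearman-Brown step-up to k measurements
        return k * r / (1.0 + (k - 1) * r)

    if average:
        est, lo, hi = icck, _sb(lo1), _sb(hi1)
    else:
        est, lo, hi = icc1, lo1, hi1
    lo, hi = min(lo, est), max(hi, est)
    return ICCResult(
        estimate=float(est),
        ci_low=float(max(lo, -1.0)),
        ci_high=float(min(hi, 1.0)),
        n_subjects=n,
        n_measurements=k,
    )


def filter_reproducible(
    t1: FeatureTable, t2: FeatureTable, threshold: float = 0.85
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features whose between-session ICC reaches ``threshold``.

    Returns the filtered session-1 table and a per-feature report with the
    ICC estimate, its 95% CI, and the keep/drop decision.  Features with
    an undefined ICC (no between-subject variance) are dropped and
    reported with NaN.
    """
    if list(t1.feature_names) != list(t2.feature_names) or not t1.data.index.equals(
        t2.data.index
    ):
        raise InputError("the two sessions must share rows and columns")

    rows = []
    for col in t1.feature_names:
        try:
            r = icc_agreement(t1.data[col].to_numpy(), t2.data[col].to_numpy())
            rows.append(
                {
                    "feature": col,
                    "icc": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "kept": r.estimate >= threshold,
                }
            )
        except UndefinedICCError:
            rows.append(
                {"feature": col, "icc": np.nan, "ci_low": np.nan, "ci_high": np.nan, "kept": False}
            )
    report = pd.DataFrame(rows).set_index("feature")
    kept = report.index[report["kept"]].tolist()
    return t1.subset(kept), report
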