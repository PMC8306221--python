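"""Univariate screening and the enter-method multivariate prediction model.

Screening is a per-feature Mann-Whitney U test with a Bonferroni-corrected
significance threshold.  Prediction is an ordinary-least-squares fit of
the 0/1 class outcome on all retained features entered in a single step
(a linear probability model), with VIF multicollinearity diagnostics and
iterative pruning of predictors whose VIF exceeds 1e4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, InputError
from .tables import FeatureTable

__all__ = [
    "mann_whitney_test",
    "bonferroni_threshold",
    "UnivariateScreenResult",
    "univariate_screen",
    "RegressionModel",
    "fit_linear_model",
    "compute_vif",
    "prune_collinear",
]


def mann_whitney_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the smaller of the two one-sided statistics.
    The p-value is exact for pooled samples of at most 20 without ties,
    otherwise the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    u = float(min(res.statistic, x.size * y.size - res.statistic))
    return u, float(min(res.pvalue, 1.0))


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-corrected significance level ``alpha / m``, truncated
    (floored) to 4 decimal places — the printed-threshold convention
    (0.05 / 30 -> 0.0016)."""
    if m < 1:
        raise InputError("family size m must be >= 1")
    return math.floor(alpha / m * 1e4) / 1e4


@dataclass
class UnivariateScreenResult:
    """Per-feature univariate comparison plus the survivor list."""

    per_feature: pd.DataFrame  # U, p, medians/IQRs per class, significant
    threshold: float
    retained: list = field(default_factory=list)


def _median_iqr(v: np.ndarray) -> tuple[float, float, float]:
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return float(med), float(q25), float(q75)


def univariate_screen(table: FeatureTable, threshold: float) -> UnivariateScreenResult:
    """Mann-Whitney comparison of every feature between the two classes.

    Features with p >= ``threshold`` are dropped from the downstream
    model; the report carries per-class medians and 25th-75th IQRs in the
    style of the univariate results table.
    """
    table.require_two_per_class()
    rows = []
    for col in table.feature_names:
        hoc, en = table.class_values(col)
        u, p = mann_whitney_test(en, hoc)
        med_en, q25_en, q75_en = _median_iqr(en)
        med_hoc, q25_hoc, q75_hoc = _median_iqr(hoc)
        rows.append(
            {
                "feature": col,
                "U": u,
                "p": p,
                "median_en": med_en,
                "iqr_en_low": q25_en,
                "iqr_en_high": q75_en,
                "median_hoc": med_hoc,
                "iqr_hoc_low": q25_hoc,
                "iqr_hoc_high": q75_hoc,
                "significant": p < threshold,
            }
        )
    per_feature = pd.DataFrame(rows).set_index("feature")
    retained = per_feature.index[per_feature["significant"]].tolist()
    return UnivariateScreenResult(per_feature=per_feature, threshold=threshold, retained=retained)


@dataclass
class RegressionModel:
    """Enter-method linear prediction model with collinearity diagnostics."""

    coefficients: pd.Series  # includes 'const'
    standard_errors: pd.Series
    p_values: pd.Series
    vif: pd.Series  # per predictor (no constant)
    r2: float
    r2_adj: float
    multiple_r: float
    model_p: float
    fitted: pd.Series  # per-lesion predicted value

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Apply the fitted linear rule to new predictor rows."""
        coef = self.coefficients
        preds = [c for c in coef.index if c != "const"]
        return X[preds] @ coef[preds] + coef.get("const", 0.0)

    @property
    def predictors(self) -> list:
        return [c for c in self.coefficients.index if c != "const"]

    def independent_predictors(self, alpha: float = 0.05) -> list:
        """Predictors whose coefficient is significant at ``alpha``."""
        return [c for c in self.predictors if self.p_values[c] < alpha]


def _r2_of_column(X: np.ndarray, j: int) -> float:
    """R^2 of column j regressed on the remaining columns plus a constant."""
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(X.shape[0]), others])
    y = X[:, j]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 1.0
    return float(1.0 - (resid**2).sum() / sst)


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1 / (1 - R_j^2) for every predictor."""
    arr = X.to_numpy(dtype=float)
    out = {}
    for j, col in enumerate(X.columns):
        r2 = _r2_of_column(arr, j)
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def prune_collinear(X: pd.DataFrame, limit: float = 1e4) -> tuple[pd.DataFrame, list]:
    """Iteratively drop the highest-VIF column while any VIF exceeds ``limit``.

    Ties break lexicographically by column name.  Returns the pruned
    frame and the dropped names in removal order.
    """
    if X.shape[1] < 2:
        return X, []
    X = X.copy()
    dropped = []
    while X.shape[1] >= 2:
        vif = compute_vif(X)
        worst = max(vif.index, key=lambda c: (vif[c], c))
        if vif[worst] <= limit:
            break
        dropped.append(worst)
        X = X.drop(columns=[worst])
    return X, dropped


def fit_linear_model(X: pd.DataFrame, y) -> RegressionModel:
    """OLS of the 0/1 outcome on all predictors entered in one step.

    Reports t-based coefficient p-values, per-predictor VIFs, R^2,
    adjusted R^2, the multiple correlation coefficient (sqrt of R^2), the
    model F-test p, and the per-lesion predicted values used downstream
    for ROC analysis.

    Raises :class:`CollinearityError` for rank-deficient designs, naming
    the offending columns.
    """
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    n, p = X.shape
    if n <= p + 1:
        raise InputError(f"need more rows ({n}) than predictors + 1 ({p + 1})")

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        arr = X.to_numpy(dtype=float)
        offending = [
            col for j, col in enumerate(X.columns) if _r2_of_column(arr, j) >= 1.0 - 1e-10
        ]
        raise CollinearityError(offending or list(X.columns))

    fit = sm.OLS(y, design).fit()
    r2 = float(fit.rsquared)
    return RegressionModel(
        coefficients=fit.params,
        standard_errors=fit.bse,
        p_values=fit.pvalues,
        vif=compute_vif(X) if p >= 2 else pd.Series({X.columns[0]: 1.0}, name="VIF"),
        r2=r2,
        r2_adj=float(fit.rsquared_adj),
        multiple_r=float(np.sqrt(max(r2, 0.0))),
        model_p=float(fit.f_pvalue),
        fitted=pd.Series(fit.fittedvalues, index=X.index, name="predicted"),
    )
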