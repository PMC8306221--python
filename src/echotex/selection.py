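"""Feature-reduction methods: Fisher coefficient, POE + ACC, and mutual
information, each returning a ranked top-k set, plus the unique-union
combiner.

All tie-breaks are lexicographic on the rendered feature name, so a given
table always yields a bit-identical selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .tables import FeatureTable

__all__ = [
    "SelectionResult",
    "fisher_score",
    "poe_single",
    "poe_acc_select",
    "mutual_information_score",
    "select_top",
    "combine_unique",
]

METHODS = ("fisher", "poe_acc", "mi")


@dataclass
class SelectionResult:
    """Ranked output of one reduction method."""

    method: str
    ranked: list  # ordered feature names, best first
    scores: pd.Series  # per-name criterion value, aligned with `ranked`


def fisher_score(class_values) -> float:
    """Ratio of between-class to within-class variance.

    ``class_values`` is a sequence of per-class value arrays.  With class
    priors P_k = n_k / n and population variances, F = D / V where
    D = sum P_k (mu_k - mu)^2 and V = sum P_k var_k.  Perfect separation
    (V = 0, D > 0) returns +inf.
    """
    groups = [np.asarray(g, dtype=float) for g in class_values]
    if any(g.size < 2 for g in groups):
        raise InputError("each class needs at least 2 values for a Fisher score")
    n = sum(g.size for g in groups)
    priors = np.array([g.size / n for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = float(priors @ means)
    D = float(priors @ (means - grand) ** 2)
    V = float(priors @ np.array([g.var() for g in groups]))
    if V == 0.0:
        return np.inf if D > 0 else 0.0
    return D / V


def poe_single(values, labels) -> tuple[float, float, str]:
    """Probability of classification error of the best single-threshold rule.

    Candidate thresholds are midpoints between sorted distinct values; both
    orientations are tried; ties resolve to the lower threshold.  Returns
    ``(poe, threshold, orientation)`` with orientation ``'>'`` meaning
    "predict class 1 when value > threshold".  A constant feature
    degenerates to the majority-class rule.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    n1 = int((labels == 1).sum())
    n0 = n - n1
    distinct = np.unique(values)
    if distinct.size < 2:
        return min(n0, n1) / n, float(distinct[0]) if distinct.size else 0.0, ">"
    mids = (distinct[:-1] + distinct[1:]) / 2.0

    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    lab1 = (labels[order] == 1).astype(int)
    # class-1 count at or below each candidate threshold
    below1 = np.searchsorted(sorted_vals, mids, side="right")
    cum1 = np.concatenate(([0], np.cumsum(lab1)))
    n1_below = cum1[below1]
    n0_below = below1 - n1_below
    # '>' rule errors: class-1 below threshold + class-0 above
    err_gt = n1_below + (n0 - n0_below)
    err_le = n - err_gt
    best_gt = int(np.argmin(err_gt))
    best_le = int(np.argmin(err_le))
    if err_gt[best_gt] <= err_le[best_le]:
        return err_gt[best_gt] / n, float(mids[best_gt]), ">"
    return err_le[best_le] / n, float(mids[best_le]), "<="


def mutual_information_score(values, labels, bins: int = 4) -> float:
    """Mutual information (bits) between a discretized feature and the class.

    The feature is cut into ``bins`` equal-frequency bins; fewer distinct
    values than bins reduces the bin count with a warning.
    """
    if bins < 2:
        raise InputError("bins must be >= 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    distinct = np.unique(values).size
    if distinct < bins:
        warnings.warn(
            f"feature has {distinct} distinct values; reducing MI bins from {bins}",
            stacklevel=2,
        )
        bins = max(distinct, 1)
    if bins == 1:
        return 0.0
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    binned = np.searchsorted(edges, values, side="left")

    classes, class_idx = np.unique(labels, return_inverse=True)
    joint = np.zeros((binned.max() + 1, classes.size))
    np.add.at(joint, (binned, class_idx), 1.0)
    joint /= joint.sum()
    pb = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pb @ pc)[nz])).sum())


def _rank_by_score(table: FeatureTable, score_fn, k: int, method: str) -> SelectionResult:
    scores = pd.Series(
        {c: score_fn(c) for c in table.feature_names}, name=method, dtype=float
    )
    # descending score, lexicographic names break ties
    order = sorted(scores.index, key=lambda c: (-scores[c], c))
    ranked = order[:k]
    return SelectionResult(method=method, ranked=ranked, scores=scores.loc[order])


def poe_acc_select(table: FeatureTable, k: int) -> SelectionResult:
    """Greedy POE + ACC selection.

    The first pick minimizes the single-feature probability of
    classification error (POE); each later pick minimizes POE(f) + ACC(f),
    where ACC is the mean absolute Pearson correlation with the features
    already selected.  Correlation with a constant column counts as 0.
    """
    if k > len(table.feature_names):
        raise InputError(f"k={k} exceeds {len(table.feature_names)} columns")
    labels = table.labels.to_numpy()
    X = table.data.to_numpy(dtype=float)
    cols = table.feature_names
    poe = np.array([poe_single(X[:, j], labels)[0] for j in range(len(cols))])

    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    n = X.shape[0]

    selected: list[int] = []
    scores: dict[str, float] = {}
    remaining = set(range(len(cols)))
    while len(selected) < k:
        if not selected:
            crit = {j: poe[j] for j in remaining}
        else:
            acc = np.abs(Z[:, sorted(selected)].T @ Z / n).mean(axis=0)
            crit = {j: poe[j] + acc[j] for j in remaining}
        best = min(remaining, key=lambda j: (crit[j], cols[j]))
        selected.append(best)
        scores[cols[best]] = float(crit[best])
        remaining.discard(best)
    ranked = [cols[j] for j in selected]
    return SelectionResult(
        method="poe_acc", ranked=ranked, scores=pd.Series(scores, name="poe_acc")
    )


def select_top(table: FeatureTable, method: str, k: int = 10) -> SelectionResult:
    """Top-k features by one reduction method (``fisher``, ``poe_acc``, ``mi``)."""
    table.require_two_per_class()
    if k > len(table.feature_names):
        raise InputError(f"k={k} exceeds {len(table.feature_names)} columns")
    if method == "fisher":
        return _rank_by_score(
            table, lambda c: fisher_score(table.class_values(c)), k, "fisher"
        )
    if method == "mi":
        labels = table.labels.to_numpy()
        return _rank_by_score(
            table,
            lambda c: mutual_information_score(table.data[c].to_numpy(), labels),
            k,
            "mi",
        )
    if method == "poe_acc":
        return poe_acc_select(table, k)
    raise InputError(f"unknown selection method {method!r}; expected one of {METHODS}")


def combine_unique(selections) -> tuple[list, dict]:
    """Union of selections preserving first-appearance order.

    Returns ``(unique_names, memberships)`` where memberships maps each
    name to the list of methods that selected it.
    """
    if not selections:
        raise InputError("at least one selection required")
    ordered: list = []
    memberships: dict = {}
    for sel in selections:
        for name in sel.ranked:
            if name not in memberships:
                memberships[name] = []
                ordered.append(name)
            memberships[name].append(sel.method)
    return ordered, memberships
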