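"""End-to-end orchestration of the two analysis branches.

The texture branch runs: feature extraction (optionally two sessions) ->
three reduction methods (top-10 each) -> unique union -> ICC
reproducibility filter -> Mann-Whitney screen at the Bonferroni-corrected
threshold -> VIF pruning -> enter-method linear model -> ROC of the model
predictions and of each independent predictor.

The ultrasound branch runs the enter-method model directly on the binary
(present/absent) grey-scale feature table and evaluates each feature and
the model predictions by ROC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyModelError, InputError
from .features import extract_table
from .io import load_grayscale, load_mask
from .reliability import filter_reproducible
from .roc import ROCResult, roc_with_delong
from .selection import SelectionResult, combine_unique, select_top
from .stats import (
    RegressionModel,
    bonferroni_threshold,
    fit_linear_model,
    prune_collinear,
    univariate_screen,
)
from .tables import FeatureTable

__all__ = [
    "PipelineConfig",
    "Report",
    "run_texture_pipeline",
    "run_us_feature_analysis",
    "load_manifest_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the workflow.

    ``bonferroni_family`` defaults to the number of unique selected
    features plus 3 (one slot for age and two for the histopathological
    entities, the convention that turns 27 unique features into a family
    of 30 and a printed threshold of 0.0016).
    """

    profile: str = "standard"
    selection_methods: tuple = ("fisher", "poe_acc", "mi")
    k: int = 10
    icc_threshold: float = 0.85
    alpha: float = 0.05
    bonferroni_family: int | None = None
    vif_limit: float = 1e4
    p_independent: float = 0.05
    seed: int = 0

    def validate(self):
        if not 0 < self.alpha < 1 or not 0 < self.p_independent < 1:
            raise InputError("alpha and p_independent must be in (0, 1)")
        if self.k < 1 or self.vif_limit <= 1:
            raise InputError("invalid k or VIF limit")


@dataclass
class Report:
    """Per-stage tables of one pipeline run.

    Every reported criterion/Se/Sp is recomputable from the stored scores
    (`model.fitted`), and ``stage_counts`` records the feature survivor
    accounting of each filter.
    """

    config: PipelineConfig
    selections: list = field(default_factory=list)
    union: list = field(default_factory=list)
    memberships: dict = field(default_factory=dict)
    icc_report: pd.DataFrame | None = None
    univariate: pd.DataFrame | None = None
    bonferroni: float | None = None
    vif_dropped: list = field(default_factory=list)
    model: RegressionModel | None = None
    roc_model: ROCResult | None = None
    roc_features: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def roc_table(self) -> pd.DataFrame:
        """ROC rows for each independent feature and the model, in the
        style of the diagnostic-performance tables."""
        rows = []
        for name, r in [*self.roc_features.items(), ("prediction model", self.roc_model)]:
            if r is None:
                continue
            rows.append(
                {
                    "feature": name,
                    "auc": r.auc,
                    "auc_ci_low": r.ci_low,
                    "auc_ci_high": r.ci_high,
                    "youden_j": r.youden_j,
                    "criterion": r.criterion_text,
                    "se_pct": 100 * r.se_opt,
                    "se_ci_low": 100 * r.se_ci[0],
                    "se_ci_high": 100 * r.se_ci[1],
                    "sp_pct": 100 * r.sp_opt,
                    "sp_ci_low": 100 * r.sp_ci[0],
                    "sp_ci_high": 100 * r.sp_ci[1],
                }
            )
        return pd.DataFrame(rows).set_index("feature")

    def model_table(self) -> pd.DataFrame:
        m = self.model
        rows = []
        for name in m.coefficients.index:
            rows.append(
                {
                    "term": name,
                    "coefficient": m.coefficients[name],
                    "standard_error": m.standard_errors[name],
                    "p": m.p_values[name],
                    "vif": m.vif.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("term")

    def write(self, outdir):
        """Write all stage tables (CSV) and a JSON run summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.univariate is not None:
            self.univariate.to_csv(outdir / "univariate.csv")
        if self.icc_report is not None:
            self.icc_report.to_csv(outdir / "icc.csv")
        if self.model is not None:
            self.model_table().to_csv(outdir / "model.csv")
            self.model.fitted.to_csv(outdir / "predicted.csv")
            self.roc_table().to_csv(outdir / "roc.csv")
        summary = {
            "stage_counts": self.stage_counts,
            "union": list(self.union),
            "memberships": {k: list(v) for k, v in self.memberships.items()},
            "vif_dropped": list(self.vif_dropped),
            "bonferroni_threshold": self.bonferroni,
        }
        if self.model is not None:
            summary["model"] = {
                "r2": self.model.r2,
                "r2_adj": self.model.r2_adj,
                "multiple_r": self.model.multiple_r,
                "model_p": self.model.model_p,
            }
        if self.roc_model is not None:
            summary["model_roc"] = {
                "auc": self.roc_model.auc,
                "criterion": self.roc_model.criterion_text,
                "se_pct": 100 * self.roc_model.se_opt,
                "sp_pct": 100 * self.roc_model.sp_opt,
            }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def load_manifest_cohort(manifest_path):
    """Read a `lesion_id,class,image_path,mask_path[,image2_path,mask2_path]`
    manifest into image/mask/label lists (and session-2 lists if present)."""
    manifest = pd.read_csv(manifest_path)
    required = {"lesion_id", "class", "image_path", "mask_path"}
    if not required.issubset(manifest.columns):
        raise InputError(f"manifest must contain columns {sorted(required)}")
    root = Path(manifest_path).parent

    def _load(img_col, mask_col):
        images, masks = [], []
        for _, row in manifest.iterrows():
            ip, mp = Path(row[img_col]), Path(row[mask_col])
            ip = ip if ip.is_absolute() else root / ip
            mp = mp if mp.is_absolute() else root / mp
            img = load_grayscale(ip)
            masks.append(load_mask(mp, img.shape))
            images.append(img)
        return images, masks

    images, masks = _load("image_path", "mask_path")
    labels = [1 if c == "EN" else 0 for c in manifest["class"]]
    ids = manifest["lesion_id"].tolist()
    session2 = None
    if {"image2_path", "mask2_path"}.issubset(manifest.columns):
        session2 = _load("image2_path", "mask2_path")
    return images, masks, labels, ids, session2


def run_texture_pipeline(
    table: FeatureTable,
    table2: FeatureTable | None = None,
    config: PipelineConfig | None = None,
) -> Report:
    """Full texture branch on extracted feature tables.

    ``table`` holds the session-1 features of every lesion; ``table2``,
    if given, the repeat-session features used for the ICC filter (the
    filter is skipped otherwise).
    """
    config = config or PipelineConfig()
    config.validate()
    table.require_two_per_class()
    report = Report(config=config)
    counts = report.stage_counts
    counts["input_features"] = len(table.feature_names)

    # 1. three reduction methods, top-k each
    report.selections = [select_top(table, m, config.k) for m in config.selection_methods]
    report.union, report.memberships = combine_unique(report.selections)
    counts["unique_selected"] = len(report.union)
    candidates = table.subset(report.union)

    # 2. reproducibility filter
    if table2 is not None:
        candidates, report.icc_report = filter_reproducible(
            candidates, table2.subset(report.union), config.icc_threshold
        )
        counts["after_icc"] = len(candidates.feature_names)
        if not candidates.feature_names:
            raise EmptyModelError("icc")

    # 3. univariate screen at the Bonferroni-corrected level
    family = config.bonferroni_family or (len(report.union) + 3)
    report.bonferroni = bonferroni_threshold(config.alpha, family)
    screen = univariate_screen(candidates, report.bonferroni)
    report.univariate = screen.per_feature
    counts["after_screen"] = len(screen.retained)
    if not screen.retained:
        raise EmptyModelError("univariate_screen")
    X = candidates.data[screen.retained]

    # 4. multicollinearity pruning, then the enter-method model
    X, report.vif_dropped = prune_collinear(X, config.vif_limit)
    counts["after_vif"] = X.shape[1]
    if X.shape[1] == 0:
        raise EmptyModelError("vif_pruning")
    report.model = fit_linear_model(X, table.labels)

    # 5. ROC of the saved predictions and of each independent predictor
    labels = table.labels.to_numpy()
    report.roc_model = roc_with_delong(report.model.fitted.to_numpy(), labels)
    for name in report.model.independent_predictors(config.p_independent):
        report.roc_features[name] = roc_with_delong(table.data[name].to_numpy(), labels)
    counts["independent_predictors"] = len(report.roc_features)
    return report


def run_pipeline_from_images(
    images, masks, labels, lesion_ids=None, session2=None, config=None
) -> Report:
    """Extract features then run the texture branch (convenience wrapper)."""
    config = config or PipelineConfig()
    table = extract_table(images, masks, labels, lesion_ids, profile=config.profile)
    table2 = None
    if session2 is not None:
        images2, masks2 = session2
        table2 = extract_table(images2, masks2, labels, lesion_ids, profile=config.profile)
    return run_texture_pipeline(table, table2, config)


def run_us_feature_analysis(
    binary_table: FeatureTable, config: PipelineConfig | None = None
) -> Report:
    """Classic binary ultrasound-feature branch.

    All present/absent (0/1) features enter the linear model in one step;
    features significant at ``p_independent`` are reported as independent
    predictors, and each feature plus the model predictions gets a ROC row.
    """
    config = config or PipelineConfig()
    config.validate()
    binary_table.require_two_per_class()
    values = binary_table.data.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise InputError("ultrasound feature tables must be binary (0 = absent, 1 = present)")

    keep = []
    for col in binary_table.feature_names:
        if binary_table.data[col].nunique() < 2:
            warnings.warn(f"dropping zero-variance ultrasound feature {col!r}", stacklevel=2)
        else:
            keep.append(col)
    if not keep:
        raise EmptyModelError("us_variance_filter")
    table = binary_table.subset(keep)

    report = Report(config=config)
    report.stage_counts["input_features"] = len(binary_table.feature_names)
    report.stage_counts["after_variance_filter"] = len(keep)
    report.model = fit_linear_model(table.data, table.labels)
    labels = table.labels.to_numpy()
    report.roc_model = roc_with_delong(report.model.fitted.to_numpy(), labels)
    for name in table.feature_names:
        report.roc_features[name] = roc_with_delong(table.data[name].to_numpy(), labels)
    report.stage_counts["independent_predictors"] = len(
        report.model.independent_predictors(config.p_independent)
    )
    return report
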