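"""Cohort feature tables: lesions x named features, with a binary label.

Class coding follows the cohort convention throughout the package:
hemorrhagic ovarian cyst (HOC) = 0, endometrioma (EN) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["FeatureTable", "HOC", "EN"]

HOC, EN = 0, 1


@dataclass
class FeatureTable:
    """Rows = lesions, columns = features, plus one 0/1 class label per row."""

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if not self.data.index.equals(self.labels.index):
            raise InputError("feature rows and labels are indexed differently")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise InputError(f"duplicate feature columns: {dups}")
        if self.data.isna().any().any():
            raise InputError("feature table contains missing values")
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise InputError("labels must be coded 0 (HOC) / 1 (EN)")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_per_class(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def require_two_per_class(self):
        n0, n1 = self.n_per_class
        if n0 < 2 or n1 < 2:
            raise InputError(f"need at least 2 lesions per class, got {n0} HOC / {n1} EN")

    def class_values(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """Values of one feature split by class: (HOC values, EN values)."""
        col = self.data[column].to_numpy(dtype=float)
        lab = self.labels.to_numpy()
        return col[lab == 0], col[lab == 1]

    def subset(self, columns) -> "FeatureTable":
        return FeatureTable(data=self.data[list(columns)].copy(), labels=self.labels.copy())

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame with the label as the leading column."""
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_column: str = "label") -> "FeatureTable":
        if label_column not in frame.columns:
            raise InputError(f"label column {label_column!r} not found")
        labels = frame[label_column].astype(int)
        return cls(data=frame.drop(columns=[label_column]).astype(float), labels=labels)

    @classmethod
    def read_csv(cls, path, label_column: str = "label") -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path, index_col=0), label_column)

    def write_csv(self, path):
        self.to_frame().to_csv(path)
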