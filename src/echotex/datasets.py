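"""Built-in small datasets.

The binary ultrasound-feature cohort here is a *synthetic* per-lesion
reconstruction: only the published per-class presence counts of the four
classic grey-scale signs are faithful; the joint assignment of features
to individual lesions is arbitrary (each feature is assigned to the first
k lesions of its class independently).  Sensitivity, specificity, and the
AUC of each single binary feature depend only on the marginal counts and
are therefore exact; joint-model coefficients are not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .roc import TwoByTwo
from .tables import FeatureTable

__all__ = ["US_FEATURE_COUNTS", "us_binary_table", "us_feature_counts_table"]

#: Published presence counts (n present in EN out of 30, in HOC out of 26)
#: for the four classic grey-scale signs of an endometrioma.
US_FEATURE_COUNTS = {
    "LowLevelEchoes": {"en": (23, 30), "hoc": (7, 26)},
    "PerceptibleWall": {"en": (17, 30), "hoc": (8, 26)},
    "NoSolidComponent": {"en": (12, 30), "hoc": (6, 26)},
    "MaxFiveLocules": {"en": (21, 30), "hoc": (26, 26)},
}


def us_binary_table(counts: dict | None = None) -> FeatureTable:
    """Synthetic 56-lesion binary table realizing the published counts."""
    counts = counts or US_FEATURE_COUNTS
    n_en = next(iter(counts.values()))["en"][1]
    n_hoc = next(iter(counts.values()))["hoc"][1]
    cols = {}
    for name, c in counts.items():
        k_en, n_en_c = c["en"]
        k_hoc, n_hoc_c = c["hoc"]
        if n_en_c != n_en or n_hoc_c != n_hoc:
            raise ValueError("inconsistent class totals across features")
        col = np.zeros(n_en + n_hoc, dtype=int)
        col[:k_en] = 1  # first k EN lesions carry the sign
        col[n_en : n_en + k_hoc] = 1
        cols[name] = col
    ids = [f"en{i:03d}" for i in range(n_en)] + [f"hoc{i:03d}" for i in range(n_hoc)]
    labels = np.concatenate([np.ones(n_en, dtype=int), np.zeros(n_hoc, dtype=int)])
    data = pd.DataFrame(cols, index=pd.Index(ids, name="lesion_id"))
    return FeatureTable(data=data, labels=pd.Series(labels, index=data.index, name="label"))


def us_feature_counts_table(name: str, predict_by_presence: bool = True) -> TwoByTwo:
    """Confusion counts of one binary sign used as an endometrioma test.

    With ``predict_by_presence`` the sign's presence predicts EN;
    otherwise its absence does (the reading used for the locule count,
    which is present in every HOC).
    """
    c = US_FEATURE_COUNTS[name]
    k_en, n_en = c["en"]
    k_hoc, n_hoc = c["hoc"]
    if predict_by_presence:
        return TwoByTwo(tp=k_en, fn=n_en - k_en, fp=k_hoc, tn=n_hoc - k_hoc)
    return TwoByTwo(tp=n_en - k_en, fn=k_en, fp=n_hoc - k_hoc, tn=k_hoc)
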