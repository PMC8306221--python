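"""Full-panel feature extraction.

``extract_all`` runs the six texture families at their conventional bit
depths (histogram 8, gradient 4, run-length 6, co-occurrence 6, AR 6,
wavelet 8) and returns a named feature vector.  The ``standard`` profile
yields exactly 275 features; ``mazda-full`` adds four extra histogram
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..io import median_despeckle, normalize_and_quantize, quantize_raw
from ..names import DIRECTIONS, FeatureName, paper_profile_names
from .ar import ar_features
from .glcm import cooccurrence_matrix, haralick_features
from .gradient import gradient_features
from .histogram import histogram_features
from .rlm import runlength_features
from .wavelet import wavelet_energy

__all__ = ["ExtractionProfile", "extract_all", "extract_table"]


@dataclass(frozen=True)
class ExtractionProfile:
    """Which features to compute, and at which per-family bit depths."""

    name: str = "standard"
    histogram_bits: int = 8
    gradient_bits: int = 4
    runlength_bits: int = 6
    cooccurrence_bits: int = 6
    ar_bits: int = 6
    wavelet_bits: int = 8
    distances: tuple = (1, 2, 3, 4, 5)
    directions: tuple = DIRECTIONS
    scales: int = 5
    despeckle: bool = False  # optional 3x3 median pre-filter
    # Histogram features default to raw display-scale intensities: absolute
    # grey values (the 10th percentile especially) are diagnostic and would
    # be destroyed by the per-ROI mu +/- 3 sigma rescaling.
    histogram_normalized: bool = False

    def feature_names(self) -> list[FeatureName]:
        return paper_profile_names(self.name)


def extract_all(img: np.ndarray, mask: np.ndarray, profile: ExtractionProfile | str = "standard") -> pd.Series:
    """Extract the full named feature panel of one lesion.

    Returns a :class:`pandas.Series` indexed by rendered feature names, in
    the canonical panel order.
    """
    if isinstance(profile, str):
        profile = ExtractionProfile(name=profile)
    if profile.despeckle:
        img = median_despeckle(img)

    quant = {
        bits: normalize_and_quantize(img, mask, bits)
        for bits in {
            profile.gradient_bits,
            profile.runlength_bits,
            profile.cooccurrence_bits,
            profile.ar_bits,
            profile.wavelet_bits,
        }
    }
    if profile.histogram_normalized:
        q_hist = quant.get(profile.histogram_bits) or normalize_and_quantize(
            img, mask, profile.histogram_bits
        )
    else:
        q_hist = quantize_raw(img, mask, profile.histogram_bits)

    hist = histogram_features(q_hist)
    grad = gradient_features(quant[profile.gradient_bits])
    rl = {
        d: runlength_features(quant[profile.runlength_bits], d) for d in profile.directions
    }
    har = {
        (d, dist): haralick_features(
            cooccurrence_matrix(quant[profile.cooccurrence_bits], d, dist)
        )
        for d in profile.directions
        for dist in profile.distances
    }
    ar = ar_features(quant[profile.ar_bits])
    wav = wavelet_energy(quant[profile.wavelet_bits], scales=profile.scales)

    values = {}
    for fn in profile.feature_names():
        key = fn.render()
        if fn.family == "histogram":
            values[key] = hist[fn.statistic]
        elif fn.family == "gradient":
            values[key] = grad[fn.statistic]
        elif fn.family == "runlength":
            values[key] = rl[fn.direction][fn.statistic]
        elif fn.family == "cooccurrence":
            values[key] = har[(fn.direction, fn.distance)][fn.statistic]
        elif fn.family == "ar":
            values[key] = ar[fn.statistic]
        else:  # wavelet
            values[key] = wav[(fn.subband, fn.scale)]
    return pd.Series(values, name="features")


def extract_table(images, masks, labels, lesion_ids=None, profile="standard"):
    """Extract the panel for a whole cohort into a :class:`FeatureTable`."""
    from ..tables import FeatureTable

    rows = [extract_all(img, m, profile) for img, m in zip(images, masks)]
    if lesion_ids is None:
        lesion_ids = [f"lesion{i:03d}" for i in range(len(rows))]
    data = pd.DataFrame(rows, index=pd.Index(lesion_ids, name="lesion_id"))
    return FeatureTable(data=data, labels=pd.Series(labels, index=data.index, name="label"))
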