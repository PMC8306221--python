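"""First-order (grey-level histogram) features.

Computed on 8-bit normalized levels.  ``Perc[n]`` is the smallest level
whose cumulative in-ROI fraction reaches n/100 — the grey value below
which n% of the ROI pixels lie.
"""

from __future__ import annotations

import numpy as np

from ..errors import TooSmallROIError
from ..io import QuantizedImage
from ._moments import population_moments

__all__ = ["histogram_features", "percentile_level"]


def percentile_level(levels: np.ndarray, pct: float) -> int:
    """Smallest level whose cumulative fraction is >= pct/100."""
    levels = np.sort(np.asarray(levels).ravel())
    n = levels.size
    # index of the first order statistic at or past the pct fraction
    idx = int(np.ceil(pct / 100.0 * n)) - 1
    return int(levels[max(idx, 0)])


def histogram_features(q: QuantizedImage, percentiles=(1, 10, 50, 90, 99)) -> dict[str, float]:
    """Mean, population variance, skewness, excess kurtosis, and percentiles
    of the in-ROI level distribution."""
    vals = q.roi_levels()
    if vals.size == 0:
        raise TooSmallROIError("empty ROI for histogram features")
    out = population_moments(vals)
    for p in percentiles:
        out[f"Perc{p:02d}"] = float(percentile_level(vals, p))
    return out
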