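"""Shared population-moment helpers.

All families use population (divide-by-N) moments; kurtosis is excess
(a normal distribution scores 0).  Zero-variance samples return 0 for
skewness and kurtosis rather than NaN.
"""

from __future__ import annotations

import numpy as np


def population_moments(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=np.float64)
    mean = float(x.mean())
    var = float(x.var())
    if var == 0.0:
        skew = kurt = 0.0
    else:
        c = x - mean
        skew = float((c**3).mean() / var**1.5)
        kurt = float((c**4).mean() / var**2 - 3.0)
    return {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
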