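"""Causal autoregressive texture model.

Each mean-centred grey level f(x, y) is modelled as a linear combination
of its four causal neighbours

    f(x, y) = th1 f(x-1, y) + th2 f(x-1, y-1) + th3 f(x, y-1)
            + th4 f(x+1, y-1) + e(x, y)

(x column, y row), fitted by least squares over all ROI pixels whose four
neighbours also lie in the ROI.  ``Sigma`` is the population standard
deviation of the residuals e.  Rank-deficient systems take the
minimum-norm solution, so a constant ROI yields th = 0, Sigma = 0.
"""

from __future__ import annotations

import numpy as np

from ..errors import TooSmallROIError
from ..io import QuantizedImage

__all__ = ["ar_features", "ar_fit"]

#: causal neighbour offsets (drow, dcol) for th1..th4
_NEIGHBOURS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))

MIN_AR_PIXELS = 5


def ar_fit(values: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Fit the 4-neighbour causal AR model on a float-valued field."""
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    h, w = values.shape

    valid = mask.copy()
    valid[0, :] = False
    valid[:, 0] = False
    valid[:, -1] = False
    shifted = []
    for dr, dc in _NEIGHBOURS:
        m = np.zeros_like(mask)
        m[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)] = mask[
            max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)
        ]
        valid &= m
        v = np.zeros_like(values)
        v[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)] = values[
            max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)
        ]
        shifted.append(v)

    n = int(valid.sum())
    if n < MIN_AR_PIXELS:
        raise TooSmallROIError(
            f"only {n} ROI pixels have a full causal neighbourhood; {MIN_AR_PIXELS} required"
        )

    centre = float(values[mask].mean())
    y = values[valid] - centre
    X = np.column_stack([s[valid] - centre for s in shifted])
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)  # minimum-norm if deficient
    resid = y - X @ theta
    return {
        "Teta1": float(theta[0]),
        "Teta2": float(theta[1]),
        "Teta3": float(theta[2]),
        "Teta4": float(theta[3]),
        "Sigma": float(resid.std()),
    }


def ar_features(q: QuantizedImage) -> dict[str, float]:
    """AR parameters on the quantized levels of the ROI."""
    return ar_fit(q.levels.astype(np.float64), q.mask)
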