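"""Absolute-gradient features.

The gradient magnitude ``sqrt(dx**2 + dy**2)`` is taken from central
differences (half the two-pixel span) at interior ROI pixels — pixels
whose full 4-neighbourhood lies inside the ROI.  Computed on 4-bit
normalized levels.
"""

from __future__ import annotations

import numpy as np

from ..errors import TooSmallROIError
from ..io import QuantizedImage
from ._moments import population_moments

__all__ = ["gradient_features", "gradient_magnitudes"]


def gradient_magnitudes(q: QuantizedImage) -> np.ndarray:
    """Central-difference gradient magnitudes at valid interior ROI pixels."""
    m = q.mask
    lv = q.levels.astype(np.float64)
    valid = np.zeros_like(m)
    valid[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    )
    if not valid.any():
        raise TooSmallROIError("no interior ROI pixel with a full 4-neighbourhood")
    dy = np.zeros_like(lv)
    dx = np.zeros_like(lv)
    dy[1:-1, :] = (lv[2:, :] - lv[:-2, :]) / 2.0
    dx[:, 1:-1] = (lv[:, 2:] - lv[:, :-2]) / 2.0
    mag = np.hypot(dx, dy)
    return mag[valid]


def gradient_features(q: QuantizedImage) -> dict[str, float]:
    """Population moments of the gradient magnitude plus the fraction of
    pixels with a nonzero gradient (``NonZeros``)."""
    mags = gradient_magnitudes(q)
    out = population_moments(mags)
    out["NonZeros"] = float((mags > 0).mean())
    return out
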