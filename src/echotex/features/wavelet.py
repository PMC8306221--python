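"""Haar wavelet energies per subband and scale.

The ROI bounding-box crop (out-of-ROI pixels filled with the in-ROI mean,
to avoid spurious edge energy from the background) is decomposed with the
Haar DWT under periodization.  ``WavEn(subband, scale)`` is the mean
squared coefficient over the coefficients whose 2^scale-pixel spatial
support intersects the ROI.

Subband letters are ordered (horizontal filter, vertical filter): HL is
high-pass along x / low-pass along y and responds to vertical edges.
A full 5-scale panel needs a bounding box of at least 32 pixels per side;
shallower boxes emit the reachable scales and 0 for the rest, with a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from ..errors import TooSmallROIError
from ..io import QuantizedImage

__all__ = ["wavelet_energy", "wavelet_energy_field"]


def _halve_mask(mask: np.ndarray) -> np.ndarray:
    """Coefficient-support mask after one dyadic decimation (2x2 block OR)."""
    h, w = mask.shape
    if h % 2:
        mask = np.vstack([mask, mask[-1:]])
    if w % 2:
        mask = np.hstack([mask, mask[:, -1:]])
    return mask.reshape(mask.shape[0] // 2, 2, mask.shape[1] // 2, 2).any(axis=(1, 3))


def wavelet_energy_field(values: np.ndarray, mask: np.ndarray, scales: int = 5) -> dict:
    """Per-(subband, scale) Haar energies of a float field inside an ROI.

    Returns a mapping ``(subband, scale) -> energy`` with subbands
    LL, LH, HL, HH and scales 1..``scales``.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise TooSmallROIError("empty ROI for wavelet energies")
    box = values[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()
    boxmask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if box.shape[0] < 2 or box.shape[1] < 2:
        raise TooSmallROIError(f"ROI bounding box {box.shape} too small for a wavelet transform")
    box[~boxmask] = values[mask].mean()

    out: dict[tuple[str, int], float] = {}
    approx, m = box, boxmask
    for s in range(1, scales + 1):
        if min(approx.shape) < 2:
            warnings.warn(
                f"ROI bounding box supports only {s - 1} wavelet scales; "
                f"deeper scales reported as 0",
                stacklevel=2,
            )
            for b in ("LL", "LH", "HL", "HH"):
                for s2 in range(s, scales + 1):
                    out[(b, s2)] = 0.0
            break
        cA, (cH, cV, cD) = pywt.dwt2(approx, "haar", mode="periodization")
        m = _halve_mask(m)
        for band, coef in (("LL", cA), ("LH", cH), ("HL", cV), ("HH", cD)):
            out[(band, s)] = float((coef[m] ** 2).mean())
        approx = cA
    return out


def wavelet_energy(q: QuantizedImage, scales: int = 5) -> dict:
    """Wavelet energies on the quantized levels of the ROI."""
    return wavelet_energy_field(q.levels.astype(np.float64), q.mask, scales=scales)
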