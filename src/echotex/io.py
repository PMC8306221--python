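"""Image and ROI loading, grey-level normalization, and quantization.

All texture families operate on a :class:`QuantizedImage`: the raw in-ROI
intensities are normalized to the window ``[mu - 3*sigma, mu + 3*sigma]``
(mu, sigma computed over the ROI itself) and binned into ``2**bits`` grey
levels.  Limiting the dynamic range to three standard deviations around the
ROI mean suppresses scanner-to-scanner brightness and contrast variation,
which would otherwise dominate every intensity-based feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import InputError, TooSmallROIError, UnsupportedFormatError

__all__ = [
    "QuantizedImage",
    "load_grayscale",
    "load_mask",
    "median_despeckle",
    "normalize_and_quantize",
    "MIN_ROI_PIXELS",
]

#: Minimum number of in-ROI pixels accepted anywhere in the pipeline.
MIN_ROI_PIXELS = 16

#: Sentinel stored in ``QuantizedImage.levels`` outside the ROI.
INVALID_LEVEL = -1


@dataclass(frozen=True)
class QuantizedImage:
    """Grey-level image reduced to ``2**bits`` levels inside an ROI.

    Attributes
    ----------
    levels
        Integer grid; in-ROI cells hold a level in ``[0, 2**bits - 1]``,
        out-of-ROI cells hold ``-1``.
    bits
        Quantization depth, one of 4, 6, 8.
    mask
        Boolean ROI grid, same shape as ``levels``.
    mu, sigma
        In-ROI mean and population standard deviation of the *source*
        intensities that defined the normalization window.
    """

    levels: np.ndarray
    bits: int
    mask: np.ndarray
    mu: float
    sigma: float

    @property
    def n_levels(self) -> int:
        return 1 << self.bits

    def roi_levels(self) -> np.ndarray:
        """Flat array of the in-ROI levels."""
        return self.levels[self.mask]


def _collapse_rgb(arr: np.ndarray) -> np.ndarray:
    # unweighted channel mean: ultrasound captures are grey-on-grey and any
    # luma convention is equivalent after the mu +/- 3 sigma normalization
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if frames > 1:
        raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"color DICOM not supported: {path}")
    return ds.pixel_array.astype(np.float64)


def load_grayscale(path) -> np.ndarray:
    """Load a 2-D grayscale image (PNG, BMP, or single-frame mono DICOM).

    Returns the intensities as stored, as a float array of shape (h, w).
    RGB inputs are collapsed by the unweighted channel mean.

    Raises
    ------
    InputError
        If the file is missing or unreadable.
    UnsupportedFormatError
        For multi-frame or color DICOM files.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in {".dcm", ".dicom"}:
        arr = _load_dicom(path)
    else:
        try:
            with Image.open(path) as im:
                arr = np.asarray(im, dtype=np.float64)
        except UnidentifiedImageError as exc:
            raise InputError(f"unreadable image file: {path}") from exc
    arr = _collapse_rgb(arr)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError(f"expected a 2-D image of at least 2x2 pixels: {path}")
    if not np.all(np.isfinite(arr)) or arr.min() < 0:
        raise InputError(f"intensities must be finite and non-negative: {path}")
    return arr


def load_mask(path, shape) -> np.ndarray:
    """Load a binary ROI mask from a PNG whose nonzero pixels mark the ROI.

    Parameters
    ----------
    shape
        Expected ``(height, width)`` of the companion image.

    Raises
    ------
    InputError
        On shape mismatch.
    TooSmallROIError
        If fewer than ``MIN_ROI_PIXELS`` pixels are inside.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such mask file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise InputError(f"unreadable mask file: {path}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    mask = np.asarray(arr) != 0
    if mask.shape != tuple(shape):
        raise InputError(f"mask shape {mask.shape} does not match image shape {tuple(shape)}")
    return validate_mask(mask)


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check an in-memory boolean ROI grid for minimal size."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < MIN_ROI_PIXELS:
        raise TooSmallROIError(f"ROI has {n} pixels; at least {MIN_ROI_PIXELS} required")
    return mask


def median_despeckle(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Optional classical despeckling: a square median filter (default off)."""
    return ndimage.median_filter(np.asarray(img, dtype=np.float64), size=size)


def quantize_raw(img: np.ndarray, mask: np.ndarray, bits: int = 8) -> QuantizedImage:
    """Quantize raw display-scale (0-255) intensities without normalization.

    Used for the histogram family, whose absolute grey values (e.g. the
    10th percentile of a near-anechoic cyst) are themselves diagnostic and
    must not be rescaled away by the per-ROI normalization.  Levels are
    ``clip(floor(v * 2**bits / 256), 0, 2**bits - 1)`` — the identity for
    8-bit input.
    """
    if bits not in (4, 6, 8):
        raise InputError(f"bits must be 4, 6 or 8, got {bits}")
    img = np.asarray(img, dtype=np.float64)
    mask = validate_mask(mask)
    if mask.shape != img.shape:
        raise InputError(f"mask shape {mask.shape} does not match image shape {img.shape}")
    vals = img[mask]
    L = 1 << bits
    levels = np.full(img.shape, INVALID_LEVEL, dtype=np.int64)
    levels[mask] = np.clip(np.floor(vals * L / 256.0), 0, L - 1).astype(np.int64)
    return QuantizedImage(
        levels=levels, bits=bits, mask=mask, mu=float(vals.mean()), sigma=float(vals.std())
    )


def normalize_and_quantize(img: np.ndarray, mask: np.ndarray, bits: int) -> QuantizedImage:
    """Normalize in-ROI grey levels to ``mu +/- 3 sigma`` and quantize.

    With ``L = 2**bits``, each in-ROI intensity ``v`` maps to

        ``clip(floor((v - (mu - 3*sigma)) * L / (6*sigma)), 0, L - 1)``

    where mu and sigma are the in-ROI mean and population standard
    deviation.  A constant ROI (sigma = 0) maps to the mid level
    ``2**(bits-1)``.  The mapping is monotone in ``v`` and invariant to
    positive affine transforms of the raw intensities.
    """
    if bits not in (4, 6, 8):
        raise InputError(f"bits must be 4, 6 or 8, got {bits}")
    img = np.asarray(img, dtype=np.float64)
    mask = validate_mask(mask)
    if mask.shape != img.shape:
        raise InputError(f"mask shape {mask.shape} does not match image shape {img.shape}")

    vals = img[mask]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population (divide-by-N) convention
    L = 1 << bits

    levels = np.full(img.shape, INVALID_LEVEL, dtype=np.int64)
    # relative test: a constant image offset by b acquires sigma ~ 1e-16 |b|
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        levels[mask] = L // 2
    else:
        scaled = np.floor((vals - (mu - 3.0 * sigma)) * L / (6.0 * sigma))
        levels[mask] = np.clip(scaled, 0, L - 1).astype(np.int64)
    return QuantizedImage(levels=levels, bits=bits, mask=mask, mu=mu, sigma=sigma)
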