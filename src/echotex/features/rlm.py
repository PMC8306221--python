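"""Run-length matrix features.

The ROI is scanned along one of four directions (H rows, V columns,
Z the SE diagonals, N the NE anti-diagonals) as maximal runs of equal
grey level; runs are truncated wherever the scan line leaves the ROI.
Computed on 6-bit normalized levels.

With r(g, k) the number of runs at level g and length k, R the total run
count and Np the in-ROI pixel count:

    ShrtREmp  = (sum r / k**2) / R      short-run emphasis
    LngREmph  = (sum r * k**2) / R      long-run emphasis
    GLevNonU  = sum_g (sum_k r)**2 / R  grey-level nonuniformity
    RLNonUni  = sum_k (sum_g r)**2 / R  run-length nonuniformity
    Fraction  = R / Np                  fraction of image in runs
"""

from __future__ import annotations

import numpy as np

from ..errors import InputError, TooSmallROIError
from ..io import QuantizedImage

__all__ = ["runlength_features", "enumerate_runs"]


def _scan_lines(levels: np.ndarray, mask: np.ndarray, direction: str):
    """Yield (levels, valid) 1-D lines along the scan direction."""
    if direction == "H":
        for r in range(levels.shape[0]):
            yield levels[r], mask[r]
    elif direction == "V":
        for c in range(levels.shape[1]):
            yield levels[:, c], mask[:, c]
    elif direction == "Z":  # SE diagonals, offset (1, 1)
        h, w = levels.shape
        for off in range(-(h - 1), w):
            yield levels.diagonal(off), mask.diagonal(off)
    elif direction == "N":  # NE anti-diagonals, offset (-1, 1)
        lv, mk = levels[::-1], mask[::-1]
        h, w = levels.shape
        for off in range(-(h - 1), w):
            yield lv.diagonal(off), mk.diagonal(off)
    else:
        raise InputError(f"unknown direction {direction!r}; expected one of H, V, N, Z")


def enumerate_runs(levels: np.ndarray, mask: np.ndarray, direction: str):
    """All (grey level, run length) pairs of the masked scan.

    Returns two integer arrays (levels, lengths), one entry per run.
    """
    gs, ks = [], []
    for line, valid in _scan_lines(levels, mask, direction):
        if not valid.any():
            continue
        line = np.asarray(line)
        valid = np.asarray(valid)
        # break runs at level changes and at ROI exits
        brk = np.flatnonzero((line[1:] != line[:-1]) | (valid[1:] != valid[:-1]))
        starts = np.concatenate(([0], brk + 1))
        ends = np.concatenate((brk + 1, [line.size]))
        keep = valid[starts]
        gs.append(line[starts[keep]])
        ks.append(ends[keep] - starts[keep])
    if not gs:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(gs), np.concatenate(ks)


def runlength_features(q: QuantizedImage, direction: str) -> dict[str, float]:
    """Run-emphasis and nonuniformity statistics for one scan direction."""
    g, k = enumerate_runs(q.levels, q.mask, direction)
    R = g.size
    if R == 0:
        raise TooSmallROIError("empty run-length scan")
    kf = k.astype(np.float64)
    np_pixels = int(q.mask.sum())
    g_counts = np.bincount(g)
    k_counts = np.bincount(k)
    return {
        "ShrtREmp": float((1.0 / kf**2).sum() / R),
        "LngREmph": float((kf**2).sum() / R),
        "GLevNonU": float((g_counts.astype(np.float64) ** 2).sum() / R),
        "RLNonUni": float((k_counts.astype(np.float64) ** 2).sum() / R),
        "Fraction": R / np_pixels,
    }
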