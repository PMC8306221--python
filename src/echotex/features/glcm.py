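"""Grey-level co-occurrence matrices and the classical Haralick statistics.

A co-occurrence matrix at offset ``(dr, dc)`` counts, symmetrically, the
ordered grey-level pairs of pixels separated by that offset with *both*
endpoints inside the ROI (no padding), then normalizes to sum 1.

Direction letters map to offsets (row, col):

    H: (0, d)    horizontal
    V: (d, 0)    vertical
    N: (-d, d)   NE diagonal
    Z: (d, d)    SE diagonal
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DegenerateMatrixError, InputError
from ..io import QuantizedImage

__all__ = ["CooccurrenceMatrix", "cooccurrence_matrix", "haralick_features", "DIRECTION_OFFSETS"]

DIRECTION_OFFSETS = {"H": (0, 1), "V": (1, 0), "N": (-1, 1), "Z": (1, 1)}


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized symmetric co-occurrence distribution ``p`` (L x L)."""

    p: np.ndarray
    direction: str
    distance: int
    bits: int

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


def cooccurrence_matrix(q: QuantizedImage, direction: str, distance: int) -> CooccurrenceMatrix:
    """Count symmetric in-ROI level pairs at the given direction/distance."""
    if direction not in DIRECTION_OFFSETS:
        raise InputError(f"unknown direction {direction!r}; expected one of H, V, N, Z")
    if not 1 <= distance <= 5:
        raise InputError(f"distance must be in 1..5, got {distance}")
    dr, dc = (distance * o for o in DIRECTION_OFFSETS[direction])
    h, w = q.levels.shape
    L = q.n_levels

    # overlap slices of the grid with itself shifted by (dr, dc)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateMatrixError(f"offset ({dr},{dc}) exceeds image extent")
    a = q.levels[r0:r1, c0:c1]
    b = q.levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    va = q.mask[r0:r1, c0:c1]
    vb = q.mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    both = va & vb
    if not both.any():
        raise DegenerateMatrixError(f"no valid in-ROI pixel pair for {direction}, d={distance}")

    i, j = a[both].ravel(), b[both].ravel()
    counts = np.zeros((L, L), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts += counts.T  # symmetric counting: each pair and its reverse
    p = counts / counts.sum()
    return CooccurrenceMatrix(p=p, direction=direction, distance=distance, bits=q.bits)


def haralick_features(P: CooccurrenceMatrix) -> dict[str, float]:
    """The 11 classical second-order statistics of a co-occurrence matrix.

    Entropies use the natural logarithm with the 0*log(0) = 0 convention.
    ``DifVarnc`` is the variance of the absolute grey-level difference
    distribution p_{x-y}; ``Contrast`` its second raw moment.  Correlation
    of a zero-variance matrix is reported as 0.
    """
    p = P.p
    L = p.shape[0]
    lv = np.arange(L, dtype=np.float64)

    px = p.sum(axis=1)  # == py by symmetry
    mu = float(lv @ px)
    var = float(((lv - mu) ** 2) @ px)

    # difference distribution over n = |i - j|
    pd = np.zeros(L)
    # sum distribution over k = i + j
    ps = np.zeros(2 * L - 1)
    ii, jj = np.indices(p.shape)
    np.add.at(pd, np.abs(ii - jj).ravel(), p.ravel())
    np.add.at(ps, (ii + jj).ravel(), p.ravel())

    nd = np.arange(L, dtype=np.float64)
    ks = np.arange(2 * L - 1, dtype=np.float64)
    mu_d = float(nd @ pd)
    sum_avg = float(ks @ ps)

    def _ent(dist):
        nz = dist[dist > 0]
        return float(-(nz * np.log(nz)).sum())

    if var > 0:
        corr = float((lv[:, None] * lv[None, :] * p).sum() - mu * mu) / var
    else:
        corr = 0.0

    return {
        "AngScMom": float((p**2).sum()),
        "Contrast": float((nd**2) @ pd),
        "Correlat": corr,
        "SumOfSqs": var,
        "InvDfMom": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "SumAverg": sum_avg,
        "SumVarnc": float(((ks - sum_avg) ** 2) @ ps),
        "SumEntrp": _ent(ps),
        "Entropy": _ent(p.ravel()),
        "DifVarnc": float(((nd - mu_d) ** 2) @ pd),
        "DifEntrp": _ent(pd),
    }
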