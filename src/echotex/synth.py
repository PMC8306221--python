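"""Synthetic ultrasound phantoms and tabular cohorts.

No public image cohort exists for this problem, so every pipeline stage
is exercised on generated data emulating the two lesion appearances:

* endometrioma-like (EN): homogeneous mid-level "ground glass" content —
  a mid base intensity carrying smoothed multiplicative Rayleigh speckle,
  with very few near-zero pixels (high 10th percentile, low contrast);
* hemorrhagic-cyst-like (HOC): near-anechoic content (low base level)
  crossed by bright reticular strands — smoothed random-walk polylines
  with a Gaussian cross-profile — and, with some probability, a
  wall-adherent clot blob (low 10th percentile, strong local variation).

Only the *orderings* of class medians are targeted (contrast-type
features higher in HOC phantoms, the 10th percentile higher in EN
phantoms); absolute feature values depend on scanner settings no
generator can reproduce.  All randomness flows through
``numpy.random.default_rng`` seeds, so a given seed yields a
bit-identical cohort on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .tables import FeatureTable

__all__ = [
    "SyntheticCohortSpec",
    "simulate_lesion_image",
    "simulate_cohort",
    "rescan_perturb",
    "simulate_feature_table",
]

#: Rayleigh scale with unit mean: E[Rayleigh(s)] = s * sqrt(pi / 2)
_UNIT_RAYLEIGH = float(1.0 / np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generator settings; the defaults define the study conditions.

    Class sizes default to the 30 EN / 26 HOC cohort composition.
    Intensities are on the 0-255 display scale.
    """

    n_en: int = 30
    n_hoc: int = 26
    image_size: int = 128
    base_en: float = 90.0  # mid-level ground-glass base intensity
    base_hoc: float = 12.0  # near-anechoic HOC background
    speckle_scale_en: float = _UNIT_RAYLEIGH  # unit-mean multiplicative speckle
    speckle_scale_hoc: float = _UNIT_RAYLEIGH
    # The ground-glass correlation length must exceed the largest
    # co-occurrence distance (5 px) or normalized contrast-type features
    # lose the EN < HOC ordering.
    smooth_sigma_en: float = 4.0  # blur width giving the homogeneous look
    smooth_sigma_hoc: float = 0.5
    strand_count: tuple = (3, 7)  # strands per HOC phantom, inclusive range
    strand_width: float = 1.3  # Gaussian cross-profile SD, pixels
    strand_gain: float = 110.0  # strand brightness above background
    clot_probability: float = 0.6  # chance of a wall-adherent bright blob
    clot_gain: float = 90.0
    clot_sigma: float = 5.0
    axes_range: tuple = (24, 44)  # ellipse semi-axes, pixels
    background_level: float = 20.0
    seed: int = 0

    def validate(self):
        if self.n_en < 0 or self.n_hoc < 0 or self.image_size < 8:
            raise InputError("invalid cohort sizes or image size")
        if not 0.0 <= self.clot_probability <= 1.0:
            raise InputError("clot_probability must be in [0, 1]")
        if 2 * self.axes_range[1] >= self.image_size:
            raise InputError("ellipse axes exceed the image")


def _ellipse_mask(size: int, rng: np.random.Generator, axes_range) -> np.ndarray:
    a = rng.uniform(*axes_range)
    b = rng.uniform(*axes_range)
    theta = rng.uniform(0, np.pi)
    cy = cx = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _draw_strands(size: int, mask: np.ndarray, spec: SyntheticCohortSpec, rng) -> np.ndarray:
    """Bright reticular strands: smoothed random-walk polylines rasterised
    with a Gaussian cross-profile."""
    canvas = np.zeros((size, size))
    rows, cols = np.nonzero(mask)
    n_strands = rng.integers(spec.strand_count[0], spec.strand_count[1] + 1)
    for _ in range(n_strands):
        i0, i1 = rng.integers(0, rows.size, size=2)
        p = np.array([rows[i0], cols[i0]], dtype=float)
        target = np.array([rows[i1], cols[i1]], dtype=float)
        n_steps = int(np.hypot(*(target - p))) * 2 + 10
        for _ in range(n_steps):
            d = target - p
            dist = np.hypot(*d)
            if dist < 1.0:
                break
            step = d / dist + rng.normal(0.0, 0.6, size=2)
            p = p + step
            r, c = int(round(p[0])), int(round(p[1]))
            if 0 <= r < size and 0 <= c < size:
                canvas[r, c] = 1.0
    canvas = ndimage.gaussian_filter(canvas, spec.strand_width)
    if canvas.max() > 0:
        canvas /= canvas.max()
    return canvas * spec.strand_gain


def _clot_blob(size: int, mask: np.ndarray, spec: SyntheticCohortSpec, rng) -> np.ndarray:
    """Wall-tangent Gaussian blob mimicking a retracting clot."""
    eroded = ndimage.binary_erosion(mask, iterations=3)
    wall = mask & ~eroded
    rows, cols = np.nonzero(wall if wall.any() else mask)
    i = rng.integers(0, rows.size)
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy - rows[i]) ** 2 + (xx - cols[i]) ** 2
    return spec.clot_gain * np.exp(-d2 / (2.0 * spec.clot_sigma**2))


def simulate_lesion_image(
    lesion_class: str, spec: SyntheticCohortSpec | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """One phantom lesion: ``(image, roi_mask)``, deterministic under seed.

    ``lesion_class`` is ``"EN"`` or ``"HOC"``.
    """
    spec = spec or SyntheticCohortSpec()
    spec.validate()
    if lesion_class not in ("EN", "HOC"):
        raise InputError(f"lesion class must be 'EN' or 'HOC', got {lesion_class!r}")
    rng = np.random.default_rng(seed)
    size = spec.image_size
    mask = _ellipse_mask(size, rng, spec.axes_range)

    img = np.full((size, size), spec.background_level)
    img = img * rng.rayleigh(_UNIT_RAYLEIGH, (size, size))

    if lesion_class == "EN":
        speckle = rng.rayleigh(spec.speckle_scale_en, (size, size))
        content = spec.base_en * ndimage.gaussian_filter(speckle, spec.smooth_sigma_en)
    else:
        speckle = rng.rayleigh(spec.speckle_scale_hoc, (size, size))
        content = spec.base_hoc * ndimage.gaussian_filter(speckle, spec.smooth_sigma_hoc)
        content = content + _draw_strands(size, mask, spec, rng)
        if rng.uniform() < spec.clot_probability:
            content = content + _clot_blob(size, mask, spec, rng)

    img[mask] = content[mask]
    return np.clip(img, 0.0, 255.0), mask


@dataclass
class CohortSim:
    """A simulated cohort: parallel lists of images, masks, labels, ids."""

    images: list
    masks: list
    labels: list  # 0 = HOC, 1 = EN
    lesion_ids: list
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_cohort(spec: SyntheticCohortSpec | None = None, outdir=None) -> CohortSim:
    """Generate ``n_en + n_hoc`` labelled phantoms.

    Per-lesion seeds are drawn from the spec seed, so the cohort is fully
    reproducible.  With ``outdir`` set, PNG images/masks and a manifest
    CSV (`lesion_id,class,image_path,mask_path`) are written there.
    """
    spec = spec or SyntheticCohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_en + spec.n_hoc)

    images, masks, labels, ids = [], [], [], []
    for i in range(spec.n_en + spec.n_hoc):
        cls = "EN" if i < spec.n_en else "HOC"
        img, m = simulate_lesion_image(cls, spec, seed=int(seeds[i]))
        images.append(img)
        masks.append(m)
        labels.append(1 if cls == "EN" else 0)
        ids.append(f"{cls.lower()}{i:03d}")

    manifest = pd.DataFrame({"lesion_id": ids, "class": ["EN" if l else "HOC" for l in labels]})
    if outdir is not None:
        from PIL import Image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        img_paths, mask_paths = [], []
        for lid, img, m in zip(ids, images, masks):
            ip, mp = outdir / f"{lid}.png", outdir / f"{lid}_mask.png"
            Image.fromarray(np.round(img).astype(np.uint8)).save(ip)
            Image.fromarray((m * 255).astype(np.uint8)).save(mp)
            # manifest paths are relative to the manifest's own directory
            img_paths.append(ip.name)
            mask_paths.append(mp.name)
        manifest["image_path"] = img_paths
        manifest["mask_path"] = mask_paths
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return CohortSim(images=images, masks=masks, labels=labels, lesion_ids=ids, manifest=manifest)


def rescan_perturb(
    img: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    mask: np.ndarray | None = None,
    jitter: bool = False,
):
    """Emulate a repeat measurement session.

    Adds seeded Gaussian intensity noise (clipped to the display range);
    with ``jitter`` and a mask given, also shifts the ROI by one pixel in
    a random direction.  Returns the perturbed image, or ``(image, mask)``
    when a mask is supplied.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.asarray(img, dtype=float)
    if noise_sd > 0:
        out = np.clip(out + rng.normal(0.0, noise_sd, out.shape), 0.0, 255.0)
    else:
        out = out.copy()
    if mask is None:
        return out
    m2 = np.asarray(mask, dtype=bool)
    if jitter:
        dr, dc = rng.integers(-1, 2, size=2)
        m2 = np.roll(np.roll(m2, int(dr), axis=0), int(dc), axis=1)
    return out, m2


def simulate_feature_table(
    n_per_class=28,
    n_informative: int = 10,
    n_noise: int = 265,
    shift_sd: float = 1.5,
    block_rho: float = 0.0,
    seed: int = 0,
) -> FeatureTable:
    """Tabular cohort with a controlled class effect.

    The informative columns share a correlated Gaussian block (pairwise
    correlation ``block_rho``) whose mean is shifted by ``shift_sd``
    standard deviations in the EN class; noise columns are iid standard
    normal.  ``n_per_class`` is an int (balanced) or a ``(n_hoc, n_en)``
    pair.
    """
    if np.isscalar(n_per_class):
        n_hoc = n_en = int(n_per_class)
    else:
        n_hoc, n_en = map(int, n_per_class)
    if n_hoc < 1 or n_en < 1 or n_informative < 0 or n_noise < 0:
        raise InputError("counts must be positive")
    if not -1.0 < block_rho < 1.0:
        raise InputError("|block_rho| must be < 1")
    rng = np.random.default_rng(seed)
    n = n_hoc + n_en
    labels = np.concatenate([np.zeros(n_hoc, dtype=int), np.ones(n_en, dtype=int)])

    cols = {}
    if n_informative:
        # equicorrelated block: shared factor sqrt(rho) + idiosyncratic part
        shared = rng.normal(size=(n, 1))
        own = rng.normal(size=(n, n_informative))
        r = max(block_rho, 0.0)
        block = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
        block[labels == 1] += shift_sd
        for i in range(n_informative):
            cols[f"inf{i + 1:02d}"] = block[:, i]
    for i in range(n_noise):
        cols[f"noise{i + 1:03d}"] = rng.normal(size=n)

    data = pd.DataFrame(cols, index=pd.Index([f"lesion{i:03d}" for i in range(n)], name="lesion_id"))
    return FeatureTable(data=data, labels=pd.Series(labels, index=data.index, name="label"))
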