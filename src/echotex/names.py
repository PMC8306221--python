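"""Feature-name grammar.

Texture features are identified by compact strings in the MaZda naming
style, e.g. ``CN5D6DifVarnc`` (co-occurrence, NE-diagonal direction,
distance 5, 6 bits, difference of variance), ``RZD6Fraction`` (run-length,
SE-diagonal), ``GD4Kurtosis`` (gradient histogram at 4 bits), ``ATeta4``
(autoregressive model), ``WavEnHL_s-2`` (wavelet energy, HL subband,
scale 2), or a bare histogram statistic such as ``Perc10``.

Rendering and parsing are exact inverses; the 275 names of the standard
profile are pairwise unique.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import InputError

__all__ = ["FeatureName", "parse_name", "paper_profile_names", "PROFILES"]

DIRECTIONS = ("H", "V", "N", "Z")

HARALICK_STATS = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)
RUNLENGTH_STATS = ("RLNonUni", "GLevNonU", "LngREmph", "ShrtREmp", "Fraction")
GRADIENT_STATS = ("Mean", "Variance", "Skewness", "Kurtosis", "NonZeros")
HISTOGRAM_STATS = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc01",
    "Perc10",
    "Perc50",
    "Perc90",
    "Perc99",
)
AR_STATS = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")
SUBBANDS = ("LL", "LH", "HL", "HH")


@dataclass(frozen=True)
class FeatureName:
    """Structured identity of one texture feature."""

    family: str  # histogram | gradient | runlength | cooccurrence | ar | wavelet
    statistic: str
    direction: Optional[str] = None  # H | V | N | Z
    distance: Optional[int] = None  # 1..5
    bits: Optional[int] = None  # 4 | 6
    scale: Optional[int] = None  # 1..5
    subband: Optional[str] = None  # LL | LH | HL | HH

    def render(self) -> str:
        f = self.family
        if f == "histogram":
            return self.statistic
        if f == "gradient":
            return f"GD{self.bits}{self.statistic}"
        if f == "runlength":
            return f"R{self.direction}D{self.bits}{self.statistic}"
        if f == "cooccurrence":
            return f"C{self.direction}{self.distance}D{self.bits}{self.statistic}"
        if f == "ar":
            return f"A{self.statistic}"
        if f == "wavelet":
            return f"WavEn{self.subband}_s-{self.scale}"
        raise InputError(f"unknown feature family: {f}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_COOC_RE = re.compile(r"^C([HVNZ])([1-5])D(4|6|8)(\w+)$")
_RL_RE = re.compile(r"^R([HVNZ])D(4|6|8)(\w+)$")
_GRAD_RE = re.compile(r"^GD(4|6|8)(\w+)$")
_WAV_RE = re.compile(r"^WavEn(LL|LH|HL|HH)_s-([1-5])$")
_AR_RE = re.compile(r"^A(Teta[1-4]|Sigma)$")


def parse_name(name: str) -> FeatureName:
    """Parse a rendered feature name back into its structured form.

    Raises :class:`~echotex.errors.InputError` for strings outside the
    grammar.
    """
    m = _COOC_RE.match(name)
    if m:
        direction, dist, bits, stat = m.groups()
        if stat not in HARALICK_STATS:
            raise InputError(f"unknown co-occurrence statistic in {name!r}")
        return FeatureName("cooccurrence", stat, direction=direction, distance=int(dist), bits=int(bits))
    m = _RL_RE.match(name)
    if m:
        direction, bits, stat = m.groups()
        if stat not in RUNLENGTH_STATS:
            raise InputError(f"unknown run-length statistic in {name!r}")
        return FeatureName("runlength", stat, direction=direction, bits=int(bits))
    m = _GRAD_RE.match(name)
    if m:
        bits, stat = m.groups()
        if stat not in GRADIENT_STATS:
            raise InputError(f"unknown gradient statistic in {name!r}")
        return FeatureName("gradient", stat, bits=int(bits))
    m = _WAV_RE.match(name)
    if m:
        subband, scale = m.groups()
        return FeatureName("wavelet", "WavEn", subband=subband, scale=int(scale))
    m = _AR_RE.match(name)
    if m:
        return FeatureName("ar", m.group(1))
    if name in HISTOGRAM_STATS:
        return FeatureName("histogram", name)
    raise InputError(f"unparseable feature name: {name!r}")


def _histogram_names(stats) -> list[FeatureName]:
    return [FeatureName("histogram", s) for s in stats]


def _gradient_names() -> list[FeatureName]:
    return [FeatureName("gradient", s, bits=4) for s in GRADIENT_STATS]


def _runlength_names() -> list[FeatureName]:
    return [
        FeatureName("runlength", s, direction=d, bits=6)
        for d in DIRECTIONS
        for s in RUNLENGTH_STATS
    ]


def _cooccurrence_names() -> list[FeatureName]:
    return [
        FeatureName("cooccurrence", s, direction=d, distance=dist, bits=6)
        for d in DIRECTIONS
        for dist in range(1, 6)
        for s in HARALICK_STATS
    ]


def _ar_names() -> list[FeatureName]:
    return [FeatureName("ar", s) for s in AR_STATS]


def _wavelet_names() -> list[FeatureName]:
    return [
        FeatureName("wavelet", "WavEn", subband=b, scale=s)
        for s in range(1, 6)
        for b in SUBBANDS
    ]


def paper_profile_names(profile: str = "standard") -> list[FeatureName]:
    """Ordered feature panel for an extraction profile.

    ``standard`` is the 275-feature panel: 5 histogram features (Mean,
    Variance, Skewness, Kurtosis, Perc10), 5 gradient, 5 run-length
    statistics x 4 directions, 11 Haralick statistics x 5 distances x 4
    directions, 5 autoregressive, 4 wavelet subbands x 5 scales.
    ``mazda-full`` adds the Perc01/50/90/99 histogram percentiles (279).
    """
    if profile == "standard":
        hist = ("Mean", "Variance", "Skewness", "Kurtosis", "Perc10")
    elif profile == "mazda-full":
        hist = HISTOGRAM_STATS
    else:
        raise InputError(f"unknown extraction profile: {profile!r}")
    return (
        _histogram_names(hist)
        + _gradient_names()
        + _runlength_names()
        + _cooccurrence_names()
        + _ar_names()
        + _wavelet_names()
    )


PROFILES = ("standard", "mazda-full")
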