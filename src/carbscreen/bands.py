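"""Parametric band shapes of the first-order carbon Raman spectrum.

The disordered-carbon spectrum is modelled as five overlapping bands: the
graphite band G (~1580 cm^-1) and the defect bands D1 (~1350), D2 (~1620,
shoulder on G), D3 (~1500, amorphous interband) and D4 (~1200, low-wavenumber
shoulder).  G, D1, D2 and D4 are Lorentzian, D3 Gaussian -- the assignment
conventionally used for poorly ordered carbonaceous matter; shapes are
configurable per band.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = ["BandShape", "Band", "BAND_NAMES", "DEFAULT_CENTERS", "DEFAULT_SHAPES",
           "evaluate_band", "evaluate_bands"]

BAND_NAMES = ("G", "D1", "D2", "D3", "D4")

#: Canonical band centers (cm^-1) for 514.5 nm excitation.
DEFAULT_CENTERS: Mapping[str, float] = {
    "G": 1580.0, "D1": 1350.0, "D2": 1620.0, "D3": 1500.0, "D4": 1200.0,
}

_FOUR_LN2 = 4.0 * math.log(2.0)


class BandShape(str, enum.Enum):
    LORENTZIAN = "lorentzian"
    GAUSSIAN = "gaussian"


#: Conventional shape assignment for disordered CM.
DEFAULT_SHAPES: Mapping[str, BandShape] = {
    "G": BandShape.LORENTZIAN,
    "D1": BandShape.LORENTZIAN,
    "D2": BandShape.LORENTZIAN,
    "D3": BandShape.GAUSSIAN,
    "D4": BandShape.LORENTZIAN,
}


@dataclass(frozen=True)
class Band:
    """One spectral band parameterised by (center, height, FWHM)."""

    name: str
    shape: BandShape
    center: float
    height: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.name not in BAND_NAMES:
            raise ValueError(f"unknown band name {self.name!r}")
        if self.height < 0:
            raise ValueError("band height must be >= 0")
        if not (0.0 < self.fwhm):
            raise ValueError("band fwhm must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return evaluate_band(self, x)

    def with_(self, **kw) -> "Band":
        return replace(self, **kw)


def evaluate_band(b: Band, x: np.ndarray) -> np.ndarray:
    """Evaluate a band on a wavenumber grid.

    Lorentzian: ``h / (1 + ((x-c)/(w/2))^2)``; Gaussian:
    ``h * exp(-4 ln2 (x-c)^2 / w^2)``.  Both peak at ``h`` at the center
    and reach ``h/2`` at ``c +/- w/2``.
    """
    x = np.asarray(x, dtype=float)
    d = x - b.center
    if b.shape is BandShape.LORENTZIAN:
        return b.height / (1.0 + (d / (b.fwhm / 2.0)) ** 2)
    return b.height * np.exp(-_FOUR_LN2 * d * d / (b.fwhm * b.fwhm))


def evaluate_bands(bands: Iterable[Band], x: np.ndarray) -> np.ndarray:
    """Sum of the evaluated bands (the spectral model)."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for b in bands:
        total += evaluate_band(b, x)
    return total
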