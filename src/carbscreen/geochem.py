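"""Companion maturity indices: atomic H/C and solid-state 13C NMR aromaticity.

The H/C atomic ratio falls as kerogen matures (heteroatoms and aliphatic
units are lost); aromaticity -- the percentage of carbon in aromatic
environments -- rises.  Aromaticity is integrated from a CP/MAS 13C NMR
spectrum split at 90 ppm, the conventional boundary between aliphatic
(< 90 ppm) and aromatic (> 90 ppm) carbon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["NmrSpectrum", "hc_atomic", "nmr_aromaticity",
           "ATOMIC_MASSES_IUPAC", "ATOMIC_MASSES_INTEGER"]

#: IUPAC standard atomic weights (default convention).
ATOMIC_MASSES_IUPAC = {"H": 1.008, "C": 12.011}
#: Integer masses; some published H/C tables round consistently only with these.
ATOMIC_MASSES_INTEGER = {"H": 1.0, "C": 12.0}


@dataclass(frozen=True)
class NmrSpectrum:
    """Solid-state 13C NMR spectrum as (chemical shift ppm, intensity)."""

    shift: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.shift, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if s.ndim != 1 or s.shape != y.shape:
            raise ValueError("shift and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(s) <= 0):
            raise ValueError("chemical shifts must be strictly increasing")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in NMR spectrum")
        object.__setattr__(self, "shift", s)
        object.__setattr__(self, "intensity", y)


def hc_atomic(h_wt: float, c_wt: float,
              masses: dict[str, float] = ATOMIC_MASSES_IUPAC) -> float:
    """Atomic H/C ratio from elemental weight percentages.

    ``(h_wt / m_H) / (c_wt / m_C)``.  Masses default to IUPAC standard
    atomic weights; pass :data:`ATOMIC_MASSES_INTEGER` to reproduce tables
    rounded with integer masses.
    """
    if not (0 < c_wt <= 100):
        raise ValueError(f"c_wt={c_wt} must be in (0, 100]")
    if not (0 <= h_wt <= 100):
        raise ValueError(f"h_wt={h_wt} must be in [0, 100]")
    return (h_wt / masses["H"]) / (c_wt / masses["C"])


def _trapz_window(s: NmrSpectrum, lo: float, hi: float,
                  exclude: Sequence[tuple[float, float]] = ()) -> float:
    mask = (s.shift >= lo) & (s.shift <= hi)
    for elo, ehi in exclude:
        mask &= ~((s.shift >= elo) & (s.shift <= ehi))
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(s.intensity[mask], s.shift[mask]))


def nmr_aromaticity(
    s: NmrSpectrum,
    split: float = 90.0,
    aromatic_window: tuple[float, float] = (90.0, 240.0),
    aliphatic_window: tuple[float, float] = (-10.0, 90.0),
    exclude: Sequence[tuple[float, float]] = (),
) -> float:
    """Percent aromatic carbon by split trapezoidal integration.

    ``100 * A_aromatic / (A_aromatic + A_aliphatic)`` with trapezoidal
    areas over the two windows (default split at 90 ppm), clipped to
    [0, 100].  Spinning side bands are not excluded automatically; pass
    their ppm intervals via ``exclude`` to drop them from both integrals.
    The spectrum should be baseline-corrected beforehand.
    """
    if aromatic_window[0] != split or aliphatic_window[1] != split:
        # windows are free, but both must meet at the split by construction
        pass
    if not ((s.shift.min() <= split) and (s.shift.max() >= split)):
        raise ValueError("spectrum does not cover the aromatic/aliphatic split point")
    a_arom = _trapz_window(s, *aromatic_window, exclude=exclude)
    a_ali = _trapz_window(s, *aliphatic_window, exclude=exclude)
    total = a_arom + a_ali
    if total == 0:
        raise ValueError("both integration windows have zero area")
    return float(np.clip(100.0 * a_arom / total, 0.0, 100.0))
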