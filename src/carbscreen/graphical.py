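"""Fit-free ("graphical") reading of R1 and FWHM-D1 from a spectrum.

When only a plotted spectrum is available, R1 and FWHM-D1 can be read
directly off the curve: R1 as the ratio of the D- and G-envelope peak
heights, FWHM-D1 as the width of the D envelope at half its height.
Because the overlapping D2-D4 bands are not separated out, this reading
carries two known biases relative to the five-band decomposition: it
underestimates R1 when a D2 shoulder is merged into the G envelope, and it
overestimates FWHM-D1 since the D3/D4 contributions broaden the D envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .decomposition import D_SEARCH_WINDOW, RamanParams
from .spectra import RamanSpectrum, check_laser

__all__ = ["SmoothingConfig", "graphical_params", "validate_graphical",
           "G_ENVELOPE_WINDOW"]

#: The G envelope is searched up to 1640 cm^-1 so that an unresolved G+D2
#: envelope is read as "the G band", reproducing the documented R1 bias.
G_ENVELOPE_WINDOW = (1560.0, 1640.0)


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay pre-smoothing; window of 1 disables smoothing."""

    window: int = 11
    order: int = 3
    allow_any_laser: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")
        if self.window > 1 and self.order >= self.window:
            raise ValueError("polynomial order must be < window")


def _peak(w: np.ndarray, y: np.ndarray, lo: float, hi: float,
          prefer: str) -> int:
    mask = (w >= lo) & (w <= hi)
    if not mask.any():
        raise ValueError(f"no data in [{lo}, {hi}]")
    sub = np.flatnonzero(mask)
    ymax = y[sub].max()
    ties = sub[y[sub] == ymax]
    return int(ties[0] if prefer == "low" else ties[-1])


def _cross_left(w, y, i_peak, level) -> float:
    """Wavenumber where the curve first falls through ``level`` left of the peak."""
    for i in range(i_peak, 0, -1):
        if y[i - 1] < level <= y[i]:
            # linear interpolation between samples i-1 and i
            t = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(w[i - 1] + t * (w[i] - w[i - 1]))
    raise ValueError("half-height level never crossed on the left flank of D")


def _cross_right(w, y, i_peak, i_stop, level) -> float | None:
    for i in range(i_peak, i_stop):
        if y[i + 1] < level <= y[i]:
            t = (level - y[i]) / (y[i + 1] - y[i])
            return float(w[i] + t * (w[i + 1] - w[i]))
    return None


def graphical_params(s: RamanSpectrum,
                     cfg: SmoothingConfig | None = None) -> RamanParams:
    """Read (R1, FWHM-D1, FWHM-G) off the curve without any band fitting.

    After optional Savitzky-Golay smoothing, R1 is the ratio of the curve
    maxima near 1350 and in the G-envelope window.  FWHM-D1 is measured at
    half the D-peak height by linear interpolation between grid points; when
    the D and G envelopes overlap so strongly that the right flank never
    reaches half height before the D/G valley, the left half-width is
    mirrored and the result flagged ``overlap_capped``.  FWHM-G is measured
    the same way on the G envelope (mirroring its right flank off the D/G
    valley side symmetrically when needed).
    """
    cfg = cfg or SmoothingConfig()
    check_laser(s, allow_any=cfg.allow_any_laser)
    w = s.wavenumber
    y = s.intensity.astype(float)
    if cfg.window > 1:
        if len(y) <= cfg.window:
            raise ValueError("spectrum shorter than the smoothing window")
        y = savgol_filter(y, cfg.window, cfg.order)

    i_d = _peak(w, y, *D_SEARCH_WINDOW, prefer="low")
    i_g = _peak(w, y, *G_ENVELOPE_WINDOW, prefer="high")
    h_d, h_g = float(y[i_d]), float(y[i_g])
    if h_d <= 0 or h_g <= 0:
        raise ValueError("missing D or G maximum")

    # valley between the D and G envelopes caps the right half-width of D
    i_valley = i_d + int(np.argmin(y[i_d:i_g + 1]))

    # ---- FWHM of the D envelope -----------------------------------------
    x_left = _cross_left(w, y, i_d, h_d / 2.0)
    left_hw = float(w[i_d]) - x_left
    x_right = _cross_right(w, y, i_d, i_valley, h_d / 2.0)
    overlap = x_right is None
    right_hw = (float(w[i_d]) - x_left) if overlap else (x_right - float(w[i_d]))
    fwhm_d1 = left_hw + right_hw

    # ---- FWHM of the G envelope (right flank free, left capped at valley)
    xg_right = _cross_right(w, y, i_g, len(w) - 1, h_g / 2.0)
    xg_left = None
    for i in range(i_g, i_valley, -1):
        if y[i - 1] < h_g / 2.0 <= y[i]:
            t = (h_g / 2.0 - y[i - 1]) / (y[i] - y[i - 1])
            xg_left = float(w[i - 1] + t * (w[i] - w[i - 1]))
            break
    if xg_right is None and xg_left is None:
        raise ValueError("G half-height level never crossed")
    g_right_hw = (xg_right - float(w[i_g])) if xg_right is not None else None
    g_left_hw = (float(w[i_g]) - xg_left) if xg_left is not None else None
    if g_right_hw is None:
        g_right_hw = g_left_hw
    if g_left_hw is None:
        g_left_hw = g_right_hw
    fwhm_g = g_left_hw + g_right_hw

    return RamanParams(r1=h_d / h_g, fwhm_d1=fwhm_d1, fwhm_g=fwhm_g,
                       method="graphical", overlap_capped=overlap)


def validate_graphical(
    benchmark: Sequence[tuple[RamanSpectrum, RamanParams]],
    cfg: SmoothingConfig | None = None,
) -> tuple[float, float]:
    """Squared OLS correlation between graphical and reference parameters.

    ``benchmark`` pairs each spectrum with reference parameters, typically
    from the five-band decomposition of the same spectrum.  Returns
    ``(r2_r1, r2_fwhm_d1)``.  Requires at least 10 spectra spanning enough
    of the maturity range that both parameter vectors vary.
    """
    if len(benchmark) < 10:
        raise ValueError("need >= 10 benchmark spectra")
    graph = np.array([(p.r1, p.fwhm_d1) for p in
                      (graphical_params(s, cfg) for s, _ in benchmark)])
    ref = np.array([(p.r1, p.fwhm_d1) for _, p in benchmark])
    out = []
    for j in range(2):
        if np.std(ref[:, j]) == 0 or np.std(graph[:, j]) == 0:
            raise ValueError("degenerate benchmark: zero variance in a parameter")
        out.append(float(np.corrcoef(graph[:, j], ref[:, j])[0, 1] ** 2))
    return out[0], out[1]
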