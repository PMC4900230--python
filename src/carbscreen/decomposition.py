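"""Constrained five-band decomposition of first-order CM Raman spectra.

The decomposition follows the screening protocol used for disordered
carbonaceous matter: a baseline-corrected first-order spectrum is modelled
as the sum of the G, D1, D2, D3 and D4 bands and fitted by bounded
nonlinear least squares.  By default the D1 height is pinned to the
observed defect-band peak height (the height of D1 is taken to be that of
the observed D envelope, which is what an operator reads off the spectrum),
and the remaining parameters are adjusted for best fit.  The screening
parameters are then

* ``R1``      -- height ratio I(D1)/I(G), rising through carbonization;
* ``FWHM-D1`` -- width of D1 (cm^-1), narrowing with structural order;
* ``FWHM-G``  -- width of G (cm^-1).

The fit is exposed statsmodels-style: build a :class:`FiveBandModel` from a
spectrum, call :meth:`~FiveBandModel.fit`, and read estimates, diagnostics
and :meth:`~FiveBandResults.summary` off the returned
:class:`FiveBandResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .bands import (BAND_NAMES, Band, BandShape, DEFAULT_CENTERS,
                    DEFAULT_SHAPES, evaluate_bands)
from .spectra import RamanSpectrum, check_laser

__all__ = ["FitConfig", "RamanParams", "FiveBandModel", "FiveBandResults",
           "initial_guess", "fit_five_bands", "params_from_fit", "replicate_params",
           "D_SEARCH_WINDOW", "G_SEARCH_WINDOW"]

#: Search window for the observed defect-band (D) peak.
D_SEARCH_WINDOW = (1300.0, 1400.0)
#: Search window for the observed graphite-band (G) envelope peak.
G_SEARCH_WINDOW = (1560.0, 1640.0)

#: Initial FWHM seeds (cm^-1) per band.
_WIDTH_SEEDS: Mapping[str, float] = {"G": 70.0, "D1": 150.0, "D2": 50.0,
                                     "D3": 150.0, "D4": 100.0}


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the five-band fit.

    Attributes
    ----------
    pin_d1 : bool
        Fix the D1 height to the observed D-envelope height instead of
        fitting it: at every model evaluation the D1 height is set so that
        the five-band total at the observed D-peak position equals the
        baseline-corrected peak intensity there (clipped at zero).  The D1
        height is thus imposed by the observed D band, never adjusted by
        the optimizer.  Disable for a fully free fit.
    center_slack : float
        Half-width (cm^-1) of the box constraining each band center around
        its canonical position.  D2 is held tighter (see
        ``center_slack_overrides``): with the generic +/-40 cm^-1 box the
        narrow D2 shoulder can slide onto the G position and swap roles
        with it, which makes R1 meaningless.
    fwhm_bounds : (float, float)
        Open interval of admissible FWHMs, cm^-1; ``fwhm_max_overrides``
        caps individual bands (D2 is a narrow shoulder, never a broad
        G-like band).
    cost_tol, max_eval :
        Optimizer termination: ftol/xtol/gtol and the model-evaluation cap.
    minor_ridge : float
        Dimensionless weight of a tiny ridge penalty on the D2/D3/D4
        heights.  The five-band parameterisation is degenerate when a minor
        band can shadow G (or D1) exactly; the ridge selects the solution
        with the smallest minor bands while perturbing well-posed fits by a
        negligible amount (height shift of order ``minor_ridge**2``).
    shapes : mapping
        Band-shape assignment; defaults to Lorentzian everywhere except the
        Gaussian D3.
    """

    pin_d1: bool = True
    center_slack: float = 40.0
    center_slack_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"D2": 20.0})
    fwhm_bounds: tuple[float, float] = (5.0, 400.0)
    fwhm_max_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"D2": 100.0})
    cost_tol: float = 1e-10
    max_eval: int = 5000
    minor_ridge: float = 0.01
    shapes: Mapping[str, BandShape] = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    allow_any_laser: bool = False


@dataclass(frozen=True)
class RamanParams:
    """The screening triple (R1, FWHM-D1, FWHM-G), with optional spreads.

    ``method`` records whether values come from the five-band decomposition
    or from the fit-free graphical reading.  ``overlap_capped`` flags a
    graphical half-width whose right flank never reached half height before
    the D/G valley (mirrored left half-width used instead).
    """

    r1: float
    fwhm_d1: float
    fwhm_g: float
    r1_sd: float | None = None
    fwhm_d1_sd: float | None = None
    fwhm_g_sd: float | None = None
    method: str = "decomposition"
    overlap_capped: bool = False

    def __post_init__(self) -> None:
        for name in ("r1", "fwhm_d1", "fwhm_g"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name}={v} must be finite and > 0")
        for name in ("r1_sd", "fwhm_d1_sd", "fwhm_g_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


def _window_peak(s: RamanSpectrum, lo: float, hi: float, prefer: str) -> tuple[float, float]:
    """(wavenumber, height) of the maximum in [lo, hi].

    Ties break deterministically: the lower-wavenumber point wins for the D
    window (``prefer='low'``), the higher for G (``prefer='high'``).
    """
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if not mask.any():
        raise ValueError(f"no data in peak window [{lo}, {hi}]")
    w, y = s.wavenumber[mask], s.intensity[mask]
    ymax = y.max()
    idx = np.flatnonzero(y == ymax)
    i = idx[0] if prefer == "low" else idx[-1]
    return float(w[i]), float(ymax)


def initial_guess(s: RamanSpectrum, cfg: FitConfig | None = None) -> list[Band]:
    """Seed the five bands from the observed D and G peak heights.

    Centers start at canonical positions; G and D1 heights at the observed
    window maxima; D2 at 10% of G and D3/D4 at 10% of D1; widths at fixed
    per-band seeds.  Raises when the spectrum shows no discernible D or G
    maximum (flat or non-positive signal).
    """
    cfg = cfg or FitConfig()
    _, h_d = _window_peak(s, *D_SEARCH_WINDOW, prefer="low")
    _, h_g = _window_peak(s, *G_SEARCH_WINDOW, prefer="high")
    floor = float(np.min(s.intensity))
    span = float(np.max(s.intensity) - floor)
    if span <= 0 or h_d <= floor or h_g <= floor:
        raise ValueError("no discernible D or G maximum (flat spectrum?)")
    heights = {"G": h_g, "D1": h_d, "D2": 0.1 * h_g, "D3": 0.1 * h_d, "D4": 0.1 * h_d}
    return [
        Band(name, cfg.shapes[name], DEFAULT_CENTERS[name],
             max(heights[name], 0.0), _WIDTH_SEEDS[name])
        for name in BAND_NAMES
    ]


@dataclass(frozen=True)
class FiveBandResults:
    """Converged five-band decomposition with diagnostics.

    Attributes mirror what a fit report needs: the five :class:`Band`
    records, the RMS residual, convergence status, the model-evaluation
    count and whether D1 was pinned.
    """

    bands: dict[str, Band]
    residual_rms: float
    initial_rms: float
    converged: bool
    n_eval: int
    d1_pinned: bool
    config: FitConfig
    spectrum: RamanSpectrum

    @property
    def params(self) -> RamanParams:
        return params_from_fit(self)

    def predict(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.spectrum.wavenumber if x is None else np.asarray(x, float)
        return evaluate_bands(self.bands.values(), x)

    def summary(self) -> str:
        lines = [
            f"Five-band decomposition of {self.spectrum.sample_id or '<spectrum>'}",
            f"  converged={self.converged}  n_eval={self.n_eval}  "
            f"residual_rms={self.residual_rms:.4g} (initial {self.initial_rms:.4g})  "
            f"d1_pinned={self.d1_pinned}",
            f"  {'band':>4} {'shape':>10} {'center':>8} {'height':>8} {'fwhm':>7}",
        ]
        for name in BAND_NAMES:
            b = self.bands[name]
            lines.append(f"  {name:>4} {b.shape.value:>10} {b.center:8.1f} "
                         f"{b.height:8.4f} {b.fwhm:7.1f}")
        p = self.params
        lines.append(f"  R1={p.r1:.3f}  FWHM-D1={p.fwhm_d1:.1f} cm-1  "
                     f"FWHM-G={p.fwhm_g:.1f} cm-1")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "bands": {n: {"shape": b.shape.value, "center": b.center,
                          "height": b.height, "fwhm": b.fwhm}
                      for n, b in self.bands.items()},
            "residual_rms": self.residual_rms,
            "initial_rms": self.initial_rms,
            "converged": self.converged,
            "n_eval": self.n_eval,
            "d1_pinned": self.d1_pinned,
        }


class FiveBandModel:
    """Five-band spectral model bound to one baseline-corrected spectrum.

    Examples
    --------
    >>> res = FiveBandModel(spectrum).fit()   # doctest: +SKIP
    >>> res.params.r1                         # doctest: +SKIP
    """

    def __init__(self, spectrum: RamanSpectrum, config: FitConfig | None = None):
        self.config = config or FitConfig()
        check_laser(spectrum, allow_any=self.config.allow_any_laser)
        self.spectrum = spectrum
        self.start = initial_guess(spectrum, self.config)

    @classmethod
    def from_file(cls, path, config: FitConfig | None = None,
                  window=(1000.0, 1800.0)) -> "FiveBandModel":
        from .spectra import crop_window, read_spectrum, subtract_linear_baseline
        s = subtract_linear_baseline(crop_window(read_spectrum(path), *window))
        return cls(s, config)

    # -- parameter packing ------------------------------------------------
    def _pack(self, bands: Sequence[Band]) -> np.ndarray:
        theta = []
        for b in bands:
            theta.append(b.center)
            if not (self.config.pin_d1 and b.name == "D1"):
                theta.append(b.height)
            theta.append(b.fwhm)
        return np.asarray(theta)

    def _unpack(self, theta: np.ndarray,
                pin: tuple[float, float] | None) -> list[Band]:
        """Rebuild the five bands; with pinning, solve D1's height so the
        model total at the observed D peak equals the observed height."""
        parts, i = {}, 0
        for name in BAND_NAMES:
            c = theta[i]; i += 1
            if pin is not None and name == "D1":
                h = None
            else:
                h = theta[i]; i += 1
            w = theta[i]; i += 1
            parts[name] = (c, h, w)

        def build(name, h):
            c, _, w = parts[name]
            return Band(name, self.config.shapes[name], c, max(h, 0.0), w)

        if pin is None:
            return [build(n, parts[n][1]) for n in BAND_NAMES]
        x_peak, y_peak = pin
        others = [build(n, parts[n][1]) for n in BAND_NAMES if n != "D1"]
        from .bands import evaluate_bands as _eb
        h_d1 = max(y_peak - float(_eb(others, np.array([x_peak]))[0]), 0.0)
        out = []
        for n in BAND_NAMES:
            out.append(build(n, h_d1) if n == "D1" else build(n, parts[n][1]))
        return out

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        hmax = 3.0 * float(np.max(self.spectrum.intensity))
        lo, hi = [], []
        for name in BAND_NAMES:
            c = DEFAULT_CENTERS[name]
            slack = cfg.center_slack_overrides.get(name, cfg.center_slack)
            lo.append(c - slack); hi.append(c + slack)
            if not (cfg.pin_d1 and name == "D1"):
                lo.append(0.0); hi.append(hmax)
            w_hi = min(cfg.fwhm_bounds[1],
                       cfg.fwhm_max_overrides.get(name, cfg.fwhm_bounds[1]))
            lo.append(cfg.fwhm_bounds[0]); hi.append(w_hi)
        return np.asarray(lo), np.asarray(hi)

    def fit(self) -> FiveBandResults:
        s, cfg = self.spectrum, self.config
        x, y = s.wavenumber, s.intensity
        pin = None
        if cfg.pin_d1:
            x_peak, y_peak = _window_peak(s, *D_SEARCH_WINDOW, prefer="low")
            pin = (x_peak, max(y_peak, 0.0))
        start = list(self.start)

        def residual(theta: np.ndarray) -> np.ndarray:
            return evaluate_bands(self._unpack(theta, pin), x) - y

        def residual_aug(theta: np.ndarray) -> np.ndarray:
            data = residual(theta)
            if cfg.minor_ridge <= 0:
                return data
            minors = [b.height for b in self._unpack(theta, pin)
                      if b.name in ("D2", "D3", "D4")]
            return np.concatenate([data, cfg.minor_ridge * np.asarray(minors)])

        theta0 = self._pack(start)
        lo, hi = self._bounds()
        theta0 = np.clip(theta0, lo, hi)
        initial_rms = float(np.sqrt(np.mean(residual(theta0) ** 2)))
        res = least_squares(
            residual_aug, theta0, bounds=(lo, hi), method="trf",
            ftol=cfg.cost_tol, xtol=cfg.cost_tol, gtol=cfg.cost_tol,
            max_nfev=cfg.max_eval,
        )
        bands = self._unpack(res.x, pin)
        rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
        return FiveBandResults(
            bands={b.name: b for b in bands},
            residual_rms=rms,
            initial_rms=initial_rms,
            converged=bool(res.status > 0),
            n_eval=int(res.nfev),
            d1_pinned=cfg.pin_d1,
            config=cfg,
            spectrum=s,
        )


def fit_five_bands(s: RamanSpectrum, cfg: FitConfig | None = None) -> FiveBandResults:
    """Fit the five-band model to one baseline-corrected spectrum."""
    return FiveBandModel(s, cfg).fit()


def params_from_fit(f: FiveBandResults) -> RamanParams:
    """Extract (R1, FWHM-D1, FWHM-G) from a converged decomposition."""
    if not f.converged:
        raise ValueError("cannot extract parameters from a non-converged fit")
    h_g = f.bands["G"].height
    if h_g <= 0:
        raise ValueError("G band height is zero; R1 undefined")
    return RamanParams(
        r1=f.bands["D1"].height / h_g,
        fwhm_d1=f.bands["D1"].fwhm,
        fwhm_g=f.bands["G"].fwhm,
        method="decomposition",
    )


def replicate_params(spectra: Sequence[RamanSpectrum],
                     cfg: FitConfig | None = None) -> RamanParams:
    """Mean and sample standard deviation of the parameters over replicate spots.

    Each replicate spectrum is decomposed independently; failures are
    reported per replicate.  Requires at least two replicates.
    """
    if len(spectra) < 2:
        raise ValueError("replicate_params needs >= 2 replicate spectra")
    values, failures = [], []
    for s in spectra:
        try:
            p = params_from_fit(fit_five_bands(s, cfg))
            values.append((p.r1, p.fwhm_d1, p.fwhm_g))
        except (ValueError, RuntimeError) as exc:
            failures.append(f"replicate {s.replicate_id} ({s.sample_id}): {exc}")
    if failures:
        raise ValueError("replicate fits failed:\n  " + "\n  ".join(failures))
    arr = np.asarray(values)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return RamanParams(
        r1=mean[0], fwhm_d1=mean[1], fwhm_g=mean[2],
        r1_sd=sd[0], fwhm_d1_sd=sd[1], fwhm_g_sd=sd[2],
        method="decomposition",
    )
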