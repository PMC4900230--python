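"""Core spectral containers and plumbing shared by all Raman operations.

A :class:`RamanSpectrum` is an ordered set of (wavenumber, intensity) pairs
covering (after cropping) the first-order region of carbonaceous matter,
roughly 1000-1800 cm^-1, where the defect (D) and graphite (G) band systems
live.  All downstream operations -- five-band decomposition, graphical
parameter reading, screening -- consume baseline-corrected spectra produced
by the helpers in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SampleRecord",
    "ALLOWED_LASERS_NM",
    "ARCHEAN_CUTOFF_GA",
    "FIRST_ORDER_WINDOW",
    "DEFAULT_BASELINE_ANCHORS",
    "read_spectrum",
    "write_spectrum",
    "crop_window",
    "subtract_linear_baseline",
    "check_laser",
    "write_table",
    "read_table",
]

#: Excitation wavelengths (nm) for which D/G height ratios are comparable;
#: screening operations refuse other lasers unless explicitly overridden.
ALLOWED_LASERS_NM = (514.5, 532.0)

#: Samples at or above this age (Ga) are treated as Archean by default.
ARCHEAN_CUTOFF_GA = 2.5

#: Default first-order fit window (cm^-1): brackets D4 (~1200) through D2 (~1620).
FIRST_ORDER_WINDOW = (1000.0, 1800.0)

#: Default anchor sub-windows for the linear baseline, at both ends of the
#: first-order window where the band system has decayed.
DEFAULT_BASELINE_ANCHORS = ((1000.0, 1100.0), (1700.0, 1800.0))


@dataclass(frozen=True)
class RamanSpectrum:
    """First-order Raman spectrum of carbonaceous matter.

    Parameters
    ----------
    wavenumber : ndarray
        Raman shift in cm^-1, strictly increasing.
    intensity : ndarray
        Intensity in arbitrary units, same length, all finite.
    sample_id : str
        Identifier of the sample (or synthetic truth tag).
    laser_nm : float
        Excitation wavelength in nm.  Height-ratio screening is only
        validated for 514.5 and 532 nm excitation.
    replicate_id : int
        Index of the acquisition spot for replicate handling.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    laser_nm: float = 514.5
    replicate_id: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumber, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavenumber and intensity must be 1-D arrays of equal length")
        if w.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumber", w)
        object.__setattr__(self, "intensity", y)

    def __len__(self) -> int:
        return self.wavenumber.size

    def with_intensity(self, intensity: np.ndarray) -> "RamanSpectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class SampleRecord:
    """Sample metadata and companion geochemical indices.

    ``is_archean`` is auto-derived from the age (>= 2.5 Ga) when not given
    explicitly.  Missing measurements are ``None`` (printed tables mark them
    "n.d."), never zero.
    """

    sample_id: str
    age_Ga: float
    facies: str = ""
    is_archean: bool | None = None
    h_wt: float | None = None
    c_wt: float | None = None
    ash: float | None = None
    aromaticity: float | None = None
    la_angstrom: float | None = None

    def __post_init__(self) -> None:
        if self.age_Ga < 0:
            raise ValueError("age_Ga must be non-negative")
        for name in ("h_wt", "c_wt", "ash", "aromaticity"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] %")
        if self.is_archean is None:
            self.is_archean = self.age_Ga >= ARCHEAN_CUTOFF_GA


def check_laser(s: RamanSpectrum, allow_any: bool = False) -> None:
    """Refuse excitation wavelengths for which R1 comparability is not established."""
    if allow_any:
        return
    if not any(abs(s.laser_nm - nm) < 0.75 for nm in ALLOWED_LASERS_NM):
        raise ValueError(
            f"laser_nm={s.laser_nm} is outside the validated set {ALLOWED_LASERS_NM}; "
            "pass allow_any_laser=True to override"
        )


def read_spectrum(
    path: str | Path,
    dialect: str = "auto",
    sample_id: str | None = None,
    laser_nm: float = 514.5,
) -> RamanSpectrum:
    """Read a two-column ASCII spectrum (wavenumber, intensity).

    Comment lines starting with ``#`` and non-numeric header lines are
    skipped.  Rows are sorted ascending in wavenumber; duplicate wavenumbers
    are averaged.  Fewer than 50 parsed points is an error: such a file
    cannot cover the first-order window meaningfully.
    """
    path = Path(path)
    seps = {"csv": ",", "tsv": "\t", "whitespace": None}
    if dialect not in ("auto", *seps):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple[float, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "auto":
            parts = line.replace(",", " ").replace(";", " ").replace("\t", " ").split()
        else:
            parts = line.split(seps[dialect])
        if len(parts) < 2:
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            continue  # header / text line
    if len(rows) < 50:
        raise ValueError(f"{path}: parsed only {len(rows)} numeric rows (need >= 50)")
    arr = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite values")
    # sort, then average duplicate wavenumbers (deterministic, order-independent)
    order = np.argsort(arr[:, 0], kind="stable")
    w, y = arr[order, 0], arr[order, 1]
    uw, inv = np.unique(w, return_inverse=True)
    if uw.size != w.size:
        sums = np.zeros(uw.size)
        counts = np.zeros(uw.size)
        np.add.at(sums, inv, y)
        np.add.at(counts, inv, 1.0)
        w, y = uw, sums / counts
    return RamanSpectrum(w, y, sample_id=sample_id or path.stem, laser_nm=laser_nm)


def write_spectrum(s: RamanSpectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column ASCII, round-trippable by read_spectrum."""
    path = Path(path)
    header = f"# sample_id={s.sample_id} laser_nm={s.laser_nm} replicate_id={s.replicate_id}\n"
    body = "\n".join(f"{w:.6g}\t{y:.6g}" for w, y in zip(s.wavenumber, s.intensity))
    path.write_text(header + body + "\n")
    return path


def crop_window(s: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Restrict a spectrum to ``lo <= wavenumber <= hi``."""
    if lo >= hi:
        raise ValueError(f"invalid window [{lo}, {hi}]")
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] contains no data points")
    return replace(s, wavenumber=s.wavenumber[mask], intensity=s.intensity[mask])


def subtract_linear_baseline(
    s: RamanSpectrum,
    anchors: Sequence[tuple[float, float]] = DEFAULT_BASELINE_ANCHORS,
) -> RamanSpectrum:
    """Subtract a straight line through the medians of two anchor sub-windows.

    Each anchor window contributes one point: (median wavenumber, median
    intensity) over the window.  The line through the two points is removed.
    Output intensities may dip slightly below zero where noise undershoots.
    """
    if len(anchors) != 2:
        raise ValueError("exactly two anchor windows required")
    pts = []
    for lo, hi in anchors:
        mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
        if not mask.any():
            raise ValueError(f"baseline anchor window [{lo}, {hi}] is empty")
        pts.append((np.median(s.wavenumber[mask]), np.median(s.intensity[mask])))
    (x0, y0), (x1, y1) = pts
    if x1 == x0:
        raise ValueError("anchor windows coincide")
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0 + slope * (s.wavenumber - x0)
    return s.with_intensity(s.intensity - baseline)


#: Fixed column order of the joined results table (mirrors the published layout).
TABLE_COLUMNS = [
    "sample_id", "age_Ga", "facies", "is_archean",
    "h_wt", "c_wt", "ash", "aromaticity", "la_angstrom",
    "r1", "r1_sd", "fwhm_d1", "fwhm_d1_sd", "fwhm_g", "fwhm_g_sd", "method",
    "stage", "on_continuum", "graphitization_suspect", "best_preserved_candidate",
    "temperature_note",
]


def write_table(records: Iterable[dict], path: str | Path) -> Path:
    """Write joined sample/parameter/assessment rows to CSV in a fixed column order.

    ``records`` are flat dicts; recognised keys are laid out first in
    :data:`TABLE_COLUMNS` order, any extras (e.g. threshold snapshots)
    follow alphabetically.  Round-trips through :func:`read_table`.
    """
    rows = list(records)
    if not rows:
        raise ValueError("refusing to write an empty results table")
    df = pd.DataFrame(rows)
    known = [c for c in TABLE_COLUMNS if c in df.columns]
    extra = sorted(c for c in df.columns if c not in TABLE_COLUMNS)
    df = df[known + extra]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_table`."""
    return pd.read_csv(path)
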