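"""Bundled reference dataset: 17 chert kerogens spanning 0.05-3.5 Ga.

The table transcribes the published characterization of seventeen chert
samples (ages, metamorphic facies, elemental H and C, ash, NMR aromaticity,
and the decomposition-derived Raman parameters with their replicate
spreads).  Entries the original table marks "n.d." are missing values here,
never zeros.  Nine of the seventeen samples are Archean (>= 2.5 Ga).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .decomposition import RamanParams
from .spectra import SampleRecord

__all__ = ["FixtureSample", "load_fixture", "fixture_frame"]


@dataclass(frozen=True)
class FixtureSample:
    """One reference sample: metadata joined with its Raman parameters."""

    record: SampleRecord
    params: RamanParams
    hc_printed: float


def _opt(v) -> float | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def fixture_frame() -> pd.DataFrame:
    """The bundled reference table as a DataFrame (missing entries are NaN)."""
    with resources.files("carbscreen.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)


def load_fixture() -> list[FixtureSample]:
    """Load the 17 reference samples with metadata and Raman parameters."""
    out = []
    for row in fixture_frame().to_dict(orient="records"):
        rec = SampleRecord(
            sample_id=row["sample_id"],
            age_Ga=float(row["age_Ga"]),
            facies=row["facies"],
            h_wt=_opt(row["h_wt"]),
            c_wt=_opt(row["c_wt"]),
            ash=_opt(row["ash"]),
            aromaticity=_opt(row["aromaticity"]),
            la_angstrom=_opt(row["la_angstrom"]),
        )
        params = RamanParams(
            r1=float(row["r1"]),
            fwhm_d1=float(row["fwhm_d1"]),
            fwhm_g=float(row["fwhm_g"]),
            r1_sd=_opt(row["r1_sd"]),
            fwhm_d1_sd=_opt(row["fwhm_d1_sd"]),
            fwhm_g_sd=_opt(row["fwhm_g_sd"]),
            method="decomposition",
        )
        out.append(FixtureSample(record=rec, params=params,
                                 hc_printed=float(row["hc_printed"])))
    return out
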