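"""Carbonization-continuum screening: staging, flags and the diagram.

Carbonaceous matter that only carbonized (never graphitized) falls on a
single trend in the (FWHM-D1, R1) plane: FWHM-D1 narrows from ~300 down to
~50 cm^-1 while R1 climbs from ~0.4 to ~2.2.  The screen places each sample
on that continuum and derives:

* a carbonization ``stage`` -- stage 1 below the R1 onset of the second
  stage (~0.8-1), stage 2 above it, and ``altered`` for the anomalous
  R1 >= 2.5 population whose molecular record is considered destroyed;
* a ``graphitization_suspect`` flag for the narrow-D1 / low-R1 corner where
  incipient graphitization pulls samples off the continuum;
* a ``best_preserved_candidate`` flag for Archean samples sitting at the
  mild-carbonization boundary (R1 0.72-1), the most promising targets for
  molecular biosignature work.

R1 ~ 1 is annotated with the ~300 degC peak-temperature association from
the Lahfid et al. RSCM calibration; no temperature is ever computed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .decomposition import RamanParams
from .spectra import SampleRecord

__all__ = ["ScreenThresholds", "MaturityAssessment", "classify",
           "cohort_ranges", "continuum_diagram", "TEMPERATURE_NOTE"]

TEMPERATURE_NOTE = ("R1 >= 1: peak temperature of roughly 300 degC "
                    "(Lahfid et al. RSCM association; annotation only)")


@dataclass(frozen=True)
class ScreenThresholds:
    """Decision thresholds of the continuum screen (all configurable).

    ``stage2_r1`` defaults to 0.9, the midpoint of the reported 0.8-1 onset
    range of the second carbonization stage.  The carbonization box extends
    to R1 2.5 so that the high-R1 end of the continuum stays on it while
    the >= 2.5 altered population is excluded.  The graphitization corner
    (FWHM-D1 <= 60 cm^-1 and R1 <= 0.7) is an operational default for the
    off-continuum partially graphitized samples, not a published criterion.
    """

    stage2_r1: float = 0.9
    altered_r1: float = 2.5
    candidate_r1_lo: float = 0.72
    candidate_r1_hi: float = 1.0
    carbonization_fwhm_d1: tuple[float, float] = (50.0, 300.0)
    carbonization_r1: tuple[float, float] = (0.4, 2.5)
    graphitization_fwhm_d1_max: float = 60.0
    graphitization_r1_max: float = 0.7

    def __post_init__(self) -> None:
        if not (self.candidate_r1_lo < self.candidate_r1_hi <= self.altered_r1):
            raise ValueError("need candidate_r1_lo < candidate_r1_hi <= altered_r1")
        for lo, hi in (self.carbonization_fwhm_d1, self.carbonization_r1):
            if lo >= hi:
                raise ValueError("empty threshold interval")


@dataclass(frozen=True)
class MaturityAssessment:
    """Outcome of the continuum screen for one sample."""

    stage: str  # "stage1" | "stage2" | "altered"
    on_continuum: bool
    graphitization_suspect: bool
    best_preserved_candidate: bool
    temperature_note: str
    thresholds: ScreenThresholds

    def to_dict(self) -> dict:
        d = {"stage": self.stage, "on_continuum": self.on_continuum,
             "graphitization_suspect": self.graphitization_suspect,
             "best_preserved_candidate": self.best_preserved_candidate,
             "temperature_note": self.temperature_note}
        d.update({f"threshold_{k}": v for k, v in asdict(self.thresholds).items()})
        return d


def classify(p: RamanParams, rec: SampleRecord,
             t: ScreenThresholds | None = None) -> MaturityAssessment:
    """Assign carbonization stage and screening flags to one sample.

    Total and deterministic on finite parameters; the stage partition by R1
    is exhaustive and mutually exclusive.
    """
    t = t or ScreenThresholds()
    if not (np.isfinite(p.r1) and np.isfinite(p.fwhm_d1)):
        raise ValueError("classify requires finite r1 and fwhm_d1")

    if p.r1 >= t.altered_r1:
        stage = "altered"
    elif p.r1 >= t.stage2_r1:
        stage = "stage2"
    else:
        stage = "stage1"

    suspect = (p.fwhm_d1 <= t.graphitization_fwhm_d1_max
               and p.r1 <= t.graphitization_r1_max)
    in_box = (t.carbonization_r1[0] <= p.r1 <= t.carbonization_r1[1]
              and t.carbonization_fwhm_d1[0] <= p.fwhm_d1 <= t.carbonization_fwhm_d1[1])
    on_continuum = in_box and not suspect
    candidate = (bool(rec.is_archean)
                 and t.candidate_r1_lo <= p.r1 <= t.candidate_r1_hi
                 and not suspect)
    note = TEMPERATURE_NOTE if p.r1 >= 1.0 else ""
    return MaturityAssessment(
        stage=stage, on_continuum=on_continuum, graphitization_suspect=suspect,
        best_preserved_candidate=candidate, temperature_note=note, thresholds=t,
    )


def cohort_ranges(
    records: Sequence[tuple[SampleRecord, RamanParams]],
) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-era (min, max) of R1, FWHM-D1 and FWHM-G.

    Groups by ``is_archean``; every group present must be non-empty (an
    absent era is simply omitted).  Returns
    ``{"archean" | "non_archean": {"r1": (lo, hi), ...}}``.
    """
    if not records:
        raise ValueError("empty sample set")
    groups: dict[str, list[RamanParams]] = {}
    for rec, p in records:
        groups.setdefault("archean" if rec.is_archean else "non_archean", []).append(p)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for era, params in groups.items():
        vals = {name: [getattr(p, name) for p in params]
                for name in ("r1", "fwhm_d1", "fwhm_g")}
        out[era] = {name: (float(min(v)), float(max(v))) for name, v in vals.items()}
    return out


def continuum_diagram(
    records: Sequence[tuple[SampleRecord, RamanParams, MaturityAssessment]],
    path: str | Path,
    thresholds: ScreenThresholds | None = None,
    descending_fwhm: bool = True,
    dpi: int = 150,
) -> Path:
    """Plot the carbonization-continuum diagram (FWHM-D1 vs R1) to a file.

    Marker convention: non-Archean open circles, Archean filled grey
    circles, graphitization suspects black triangles, altered samples red
    crosses.  Threshold guides (stage-2 onset, altered cut, candidate band)
    are drawn; empty marker classes are left out of the legend.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("nothing to plot")
    t = thresholds or records[0][2].thresholds
    fig, ax = plt.subplots(figsize=(6.5, 5))

    def _sel(pred):
        return [(p.fwhm_d1, p.r1) for rec, p, a in records if pred(rec, a)]

    classes = [
        (_sel(lambda r, a: a.graphitization_suspect),
         dict(marker="^", c="black", label="graphitization suspect")),
        (_sel(lambda r, a: a.stage == "altered" and not a.graphitization_suspect),
         dict(marker="x", c="tab:red", label="altered (R1 >= 2.5)")),
        (_sel(lambda r, a: r.is_archean and a.stage != "altered"
              and not a.graphitization_suspect),
         dict(marker="o", c="0.45", label="Archean")),
        (_sel(lambda r, a: not r.is_archean and a.stage != "altered"
              and not a.graphitization_suspect),
         dict(marker="o", facecolors="none", edgecolors="black", label="non-Archean")),
    ]
    for pts, style in classes:
        if pts:
            xs, ys = zip(*pts)
            ax.scatter(xs, ys, s=45, **style)
    ax.axhline(t.stage2_r1, ls="--", lw=0.8, c="0.5")
    ax.axhline(t.altered_r1, ls=":", lw=0.8, c="tab:red")
    ax.axhspan(t.candidate_r1_lo, t.candidate_r1_hi, color="tab:green", alpha=0.08,
               label="candidate R1 band")
    ax.set_xlabel("FWHM-D1 (cm$^{-1}$)")
    ax.set_ylabel("R1 = I(D1)/I(G)")
    ax.set_title("Carbonization continuum")
    if descending_fwhm:
        ax.invert_xaxis()
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
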