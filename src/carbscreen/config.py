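"""Run configuration: structured settings, TOML loading, config hashing.

A :class:`RunConfig` bundles every knob of a screening run (fit settings,
smoothing, thresholds, seed) so that outputs can embed the effective
configuration and a short hash of it for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .bands import BandShape
from .decomposition import FitConfig
from .graphical import SmoothingConfig
from .screen import ScreenThresholds

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a screening run."""

    fit: FitConfig = field(default_factory=FitConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    window: tuple[float, float] = (1000.0, 1800.0)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"]["shapes"] = {k: (v.value if isinstance(v, BandShape) else v)
                              for k, v in d["fit"]["shapes"].items()}
        return d


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a TOML file; absent keys keep their defaults."""
    raw = tomllib.loads(Path(path).read_text())
    fit_kw = dict(raw.get("fit", {}))
    if "shapes" in fit_kw:
        fit_kw["shapes"] = {k: BandShape(v) for k, v in fit_kw["shapes"].items()}
    thr_kw = {k: tuple(v) if isinstance(v, list) else v
              for k, v in raw.get("thresholds", {}).items()}
    return RunConfig(
        fit=FitConfig(**fit_kw),
        smoothing=SmoothingConfig(**raw.get("smoothing", {})),
        thresholds=ScreenThresholds(**thr_kw),
        window=tuple(raw.get("window", (1000.0, 1800.0))),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
    )


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the effective configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
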