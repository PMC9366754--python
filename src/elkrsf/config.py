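"""Pipeline configuration: a single YAML/JSON-serialisable structure.

Defaults equal the study design: 500/1000 second-order points, 10:1
third-order ratio, Jul 1–Aug 31 season with 11:00–18:00 censoring, 99%
isopleths, available weight 1000, Normal(0,2)/Uniform(0,2) priors,
fivefold cross-validation with 5 habitat bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "apply_overrides"]


@dataclass
class PipelineConfig:
    # inputs (None = simulate)
    telemetry_path: str | None = None
    de_path: str | None = None
    lion_path: str | None = None
    wolf_path: str | None = None
    demography_path: str | None = None
    outdir: str = "runs/latest"

    # season / time filters
    season_start: str = "07-01"
    season_end: str = "08-31"
    rest_start: str = "11:00"
    rest_end: str = "18:00"

    # home ranges
    isopleth_level: float = 0.99
    grid_resolution: float = 250.0

    # design
    n_used_second: int = 500
    n_avail_second: int = 1000
    third_order_ratio: int = 10
    available_weight: float = 1000.0

    # model priors (scales are standard deviations)
    fixed_prior_scale: float = 2.0
    intercept_ranef_scale: float = 100.0
    slope_sd_upper: float = 2.0

    # estimation
    method: str = "laplace"
    draws: int = 400
    mcmc_walkers: int = 32
    mcmc_warmup: int = 400
    mcmc_steps: int = 400

    # validation
    cv_folds: int = 5
    cv_bins: int = 5

    # trade-off
    de_quantile: float = 0.95
    risk_hi_quantile: float = 0.95
    risk_lo_quantile: float = 0.05

    # synthetic scenario
    n_individuals: int = 40
    n_fixes: int = 640
    raster_shape: tuple[int, int] = (256, 256)
    cell_size: float = 250.0
    smoothness: float = 8.0
    hr_radius: float = 3000.0
    sigma: float = 0.15

    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["raster_shape"] = list(d["raster_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "raster_shape" in d:
            d = dict(d)
            d["raster_shape"] = tuple(d["raster_shape"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def apply_overrides(config: PipelineConfig, overrides: list[str]) -> PipelineConfig:
    """Apply ``key=value`` overrides, parsing values as YAML scalars."""
    d = config.to_dict()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must be key=value, got {item!r}")
        key, raw = item.split("=", 1)
        if key not in d:
            raise ValueError(f"unknown config key {key!r}")
        d[key] = yaml.safe_load(raw)
    return PipelineConfig.from_dict(d)
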