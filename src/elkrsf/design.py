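"""Used–available design tables for second- and third-order selection.

Second order contrasts each individual's home range (500 uniform "used"
points) against its population summer range (1000 "available" points).
Third order contrasts observed foraging fixes against 10 uniform available
points per used fix within the individual's home range.  Available rows
carry weight 1000 and used rows weight 1, the infinitely-weighted logistic
approximation to the inhomogeneous point-process likelihood.

Covariates (DE, and log predator relative use ML/WF) are centred and
scaled to unit sample standard deviation over the pooled table of each
order; the constants are recorded so predictions can be mapped back to
raw units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .homerange import HomeRange, sample_uniform_in_polygon
from .raster import RasterSurface, extract_covariates

__all__ = [
    "Standardization",
    "DegenerateCovariateError",
    "standardize_covariates",
    "build_second_order_table",
    "build_third_order_table",
    "covariate_correlations",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

COVARIATES = ["de", "ml", "wf"]
USED_WEIGHT = 1.0
AVAILABLE_WEIGHT = 1000.0


class DegenerateCovariateError(ValueError):
    """A covariate column is constant and cannot be standardized."""


@dataclass
class Standardization:
    """Per-covariate centring/scaling constants (sample sd, n-1 denominator)."""

    means: dict[str, float]
    sds: dict[str, float]

    def apply(self, df: pd.DataFrame, columns=COVARIATES) -> pd.DataFrame:
        out = df.copy()
        for c in columns:
            out[c] = (df[c] - self.means[c]) / self.sds[c]
        return out

    def invert(self, df: pd.DataFrame, columns=COVARIATES) -> pd.DataFrame:
        out = df.copy()
        for c in columns:
            out[c] = df[c] * self.sds[c] + self.means[c]
        return out

    def transform_values(self, column: str, values):
        return (np.asarray(values, float) - self.means[column]) / self.sds[column]

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds, "sd_convention": "sample (n-1)"}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


def standardize_covariates(
    table: pd.DataFrame,
    columns=COVARIATES,
    constants: Standardization | None = None,
    correlation_warn: float = 0.50,
) -> tuple[pd.DataFrame, Standardization]:
    """Centre and scale covariate columns; report pairwise correlations.

    Uses the sample standard deviation (n-1).  A constant column raises
    :class:`DegenerateCovariateError`.  Any pairwise |r| above
    ``correlation_warn`` emits a collinearity warning (the design aims to
    keep all pairwise correlations at or below 0.50).
    """
    vals = table[list(columns)].to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("covariate columns must be finite")
    if constants is None:
        means, sds = {}, {}
        for c in columns:
            m = float(table[c].mean())
            s = float(table[c].std(ddof=1))
            if not np.isfinite(s) or s == 0:
                raise DegenerateCovariateError(f"covariate {c!r} is constant")
            means[c], sds[c] = m, s
        constants = Standardization(means, sds)
    out = constants.apply(table, columns)
    corr = out[list(columns)].corr()
    for i, a in enumerate(columns):
        for b in list(columns)[i + 1 :]:
            r = float(corr.loc[a, b])
            if abs(r) > correlation_warn:
                warnings.warn(
                    f"covariates {a!r} and {b!r} are correlated (r = {r:.3f} "
                    f"> {correlation_warn})",
                    stacklevel=2,
                )
    return out, constants


def covariate_correlations(table: pd.DataFrame, columns=COVARIATES) -> pd.DataFrame:
    """Pairwise Pearson correlations and R^2 between covariates.

    Exposed as a diagnostic: the correlation of predator risk with
    digestible energy is what creates the potential for a forage-risk
    trade-off in the first place.
    """
    corr = table[list(columns)].corr()
    return pd.DataFrame({"r": corr.stack(), "r2": (corr**2).stack()})


def _assemble(rows_used: pd.DataFrame, rows_avail: pd.DataFrame,
              individual_id: str, order: str) -> pd.DataFrame:
    rows_used = rows_used.assign(used=1, weight=USED_WEIGHT)
    rows_avail = rows_avail.assign(used=0, weight=AVAILABLE_WEIGHT)
    df = pd.concat([rows_used, rows_avail], ignore_index=True)
    df.insert(0, "individual_id", individual_id)
    df.insert(1, "order", order)
    return df


def build_second_order_table(
    individual_hrs: dict[str, HomeRange],
    population_hr: HomeRange | dict[str, HomeRange],
    de: RasterSurface,
    lion: RasterSurface,
    wolf: RasterSurface,
    n_used: int = 500,
    n_avail: int = 1000,
    seed: int | np.random.Generator | None = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, Standardization | None]:
    """Second-order design: home ranges within the population summer range.

    Per individual, ``n_used`` uniform points in its home range (the used
    sample) and ``n_avail`` uniform points in its population range (the
    available sample).  ``population_hr`` may be a single range or a
    mapping individual -> population range (for multiple herd units).
    """
    rng = np.random.default_rng(seed)
    parts = []
    for ind, hr in individual_hrs.items():
        pop = population_hr[ind] if isinstance(population_hr, dict) else population_hr
        used_pts = sample_uniform_in_polygon(hr, n_used, rng)
        avail_pts = sample_uniform_in_polygon(pop, n_avail, rng)
        used = extract_covariates(used_pts, de, lion, wolf)
        avail = extract_covariates(avail_pts, de, lion, wolf)
        parts.append(_assemble(used, avail, ind, "second"))
    table = pd.concat(parts, ignore_index=True)
    if not standardize:
        return table, None
    std_table, constants = standardize_covariates(table)
    return std_table, constants


def build_third_order_table(
    used: pd.DataFrame,
    individual_hrs: dict[str, HomeRange],
    de: RasterSurface,
    lion: RasterSurface,
    wolf: RasterSurface,
    ratio: int = 10,
    seed: int | np.random.Generator | None = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, Standardization | None]:
    """Third-order design: foraging fixes within the individual home range.

    ``used`` must already be season/time filtered telemetry.  Each
    individual with U used fixes gets ``ratio * U`` available points
    sampled uniformly in its home range.  Individuals with no used fixes
    are dropped with a logged warning.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for ind, hr in individual_hrs.items():
        fixes = used[used["animal_id"].astype(str) == str(ind)]
        if len(fixes) == 0:
            logger.warning("individual %s has no used locations after filtering; excluded", ind)
            continue
        used_cov = extract_covariates(fixes[["x", "y"]].to_numpy(float), de, lion, wolf)
        avail_pts = sample_uniform_in_polygon(hr, ratio * len(fixes), rng)
        avail_cov = extract_covariates(avail_pts, de, lion, wolf)
        parts.append(_assemble(used_cov, avail_cov, ind, "third"))
    if not parts:
        raise ValueError("no individual had used locations")
    table = pd.concat(parts, ignore_index=True)
    if not standardize:
        return table, None
    std_table, constants = standardize_covariates(table)
    return std_table, constants


def write_table(table: pd.DataFrame, constants: Standardization | None,
                path: str | Path, seed: int | None = None) -> None:
    """Write a used–available table as CSV plus a JSON sidecar of constants."""
    path = Path(path)
    cols = ["individual_id", "order", "used", "weight", "de", "ml", "wf"]
    extra = [c for c in ("x", "y") if c in table.columns]
    table[cols + extra].to_csv(path, index=False)
    sidecar = {"seed": seed}
    if constants is not None:
        sidecar["standardization"] = constants.to_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_table(path: str | Path) -> tuple[pd.DataFrame, Standardization | None]:
    path = Path(path)
    table = pd.read_csv(path, dtype={"individual_id": str})
    constants = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "standardization" in meta:
            constants = Standardization.from_dict(meta["standardization"])
    return table, constants
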