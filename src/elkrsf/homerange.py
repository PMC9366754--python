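"""Kernel utilization distributions, isopleth home ranges and polygon sampling.

The utilization distribution (UD) is estimated with a fixed (single global
bandwidth) Gaussian kernel, evaluated exactly on a regular grid via the
separable product of the per-axis kernels.  Home ranges are the isopleth
contours of the UD enclosing a stated fraction of the estimated use (the
study design uses the 99% isopleth), extracted by marching squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure

from .raster import RasterSurface

__all__ = [
    "InsufficientDataError",
    "HomeRange",
    "reference_bandwidth",
    "estimate_kde_ud",
    "extract_isopleth",
    "sample_uniform_in_polygon",
    "clip_home_range",
    "estimate_home_range",
]


class InsufficientDataError(ValueError):
    """Too few locations to estimate a utilization distribution."""


@dataclass
class HomeRange:
    """An isopleth home range: one or more simple planar polygons."""

    geometry: MultiPolygon
    isopleth_level: float
    bandwidth: tuple[float, float]
    grid_resolution: float
    owner: str = "population"
    enclosed_mass: float = float("nan")

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    def to_wkt(self) -> str:
        return self.geometry.wkt

    def contains(self, x, y) -> np.ndarray:
        return shapely.contains_xy(self.geometry, np.asarray(x, float), np.asarray(y, float))


def reference_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Ad hoc ("reference") per-axis bandwidth h = sigma * n^(-1/6).

    This is the common default of kernel home-range tooling in movement
    ecology: optimal for an underlying bivariate normal, oversmoothed
    otherwise, which is the accepted bias for stable isopleths.
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    sx = pts[:, 0].std(ddof=1)
    sy = pts[:, 1].std(ddof=1)
    factor = n ** (-1.0 / 6.0)
    return (max(sx * factor, 1e-12), max(sy * factor, 1e-12))


def estimate_kde_ud(
    locations: pd.DataFrame | np.ndarray,
    bandwidth: tuple[float, float] | float | None = None,
    grid_resolution: float = 250.0,
    pad_sd: float = 4.0,
    grid_shape: tuple[int, int] | None = None,
) -> tuple[RasterSurface, tuple[float, float]]:
    """Estimate the UD on a regular grid with a fixed Gaussian kernel.

    Parameters
    ----------
    locations
        Telemetry table (``x``/``y`` columns) or an ``(n, 2)`` array.
    bandwidth
        Per-axis (hx, hy) in metres, a single scalar for both axes, or
        None for the reference rule.
    grid_resolution
        Cell size of the evaluation grid, metres.
    pad_sd
        Grid margin beyond the data bounding box, in bandwidths.
    grid_shape
        Force an exact (n_rows, n_cols) grid (overrides the padding rule).

    Returns the UD raster (density per m^2; integrates to 1) and the
    bandwidth actually used.
    """
    if hasattr(locations, "columns"):
        pts = locations[["x", "y"]].to_numpy(float)
    else:
        pts = np.asarray(locations, float).reshape(-1, 2)
    n = pts.shape[0]
    if n < 5:
        raise InsufficientDataError(f"need at least 5 locations, got {n}")
    if bandwidth is None:
        hx, hy = reference_bandwidth(pts)
    elif np.isscalar(bandwidth):
        hx = hy = float(bandwidth)
    else:
        hx, hy = (float(bandwidth[0]), float(bandwidth[1]))
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive")

    res = float(grid_resolution)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    if grid_shape is None:
        ox = xmin - pad_sd * hx
        oy = ymin - pad_sd * hy
        n_cols = max(int(np.ceil((xmax + pad_sd * hx - ox) / res)), 1)
        n_rows = max(int(np.ceil((ymax + pad_sd * hy - oy) / res)), 1)
    else:
        n_rows, n_cols = grid_shape
        cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
        ox = cx - n_cols * res / 2
        oy = cy - n_rows * res / 2

    xs = ox + (np.arange(n_cols) + 0.5) * res
    ys = oy + (np.arange(n_rows) + 0.5) * res
    # separable Gaussian product: density = Gy @ Gx^T / n, evaluated exactly
    gx = np.exp(-0.5 * ((xs[:, None] - pts[None, :, 0]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    gy = np.exp(-0.5 * ((ys[:, None] - pts[None, :, 1]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = (gy @ gx.T) / n  # (n_rows bottom-up, n_cols)
    density = density[::-1, :]  # row 0 = north
    ud = RasterSurface(density, ox, oy, res)
    return ud, (hx, hy)


def _isopleth_threshold(density: np.ndarray, cell_area: float, level: float) -> float:
    """Density cutoff whose superlevel set first encloses >= level UD mass."""
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    idx = int(np.searchsorted(cum, level))
    idx = min(idx, flat.size - 1)
    return float(flat[idx])


def extract_isopleth(
    ud: RasterSurface,
    level: float = 0.99,
    owner: str = "population",
    bandwidth: tuple[float, float] = (float("nan"), float("nan")),
) -> HomeRange:
    """Extract the isopleth polygon(s) enclosing ``level`` of the UD mass.

    The superlevel set of the density at the mass-matching cutoff is
    contoured with marching squares; contours nested inside another
    contour an odd number of times become holes.
    """
    if not 0 < level <= 1:
        raise ValueError(f"isopleth level must be in (0, 1], got {level}")
    density = ud.values[::-1, :]  # bottom-up for coordinate math
    cell_area = ud.cell_size**2
    total = density.sum() * cell_area
    if not np.isfinite(total) or total <= 0:
        raise ValueError("utilization distribution has no mass")
    if level == 1.0:
        # limit case: every cell with nonzero density
        tau = np.nextafter(0.0, 1.0)
    else:
        tau = _isopleth_threshold(density, cell_area, level * total)
    mask = density >= tau
    enclosed = float(density[mask].sum() * cell_area / total)

    # pad with zeros so contours on the data margin close
    padded = np.pad(density, 1, constant_values=0.0)
    contours = measure.find_contours(padded, tau if level < 1.0 else tau / 2)
    xs0 = ud.origin_x + 0.5 * ud.cell_size
    ys0 = ud.origin_y + 0.5 * ud.cell_size
    polys: list[Polygon] = []
    for c in contours:
        if len(c) < 4:
            continue
        # padded array index -> cell-centre world coordinates
        x = xs0 + (c[:, 1] - 1) * ud.cell_size
        y = ys0 + (c[:, 0] - 1) * ud.cell_size
        p = Polygon(np.column_stack([x, y]))
        if p.is_valid and p.area > 0:
            polys.append(p)
    if not polys:
        raise ValueError("no isopleth contour found (degenerate density)")

    polys.sort(key=lambda p: p.area, reverse=True)
    depth = [sum(1 for q in polys if q is not p and q.contains(p)) for p in polys]
    shells = [p for p, d in zip(polys, depth) if d % 2 == 0]
    holes = [p for p, d in zip(polys, depth) if d % 2 == 1]
    geom = unary_union(shells)
    if holes:
        geom = geom.difference(unary_union(holes))
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return HomeRange(
        geometry=geom,
        isopleth_level=level,
        bandwidth=tuple(bandwidth),
        grid_resolution=ud.cell_size,
        owner=owner,
        enclosed_mass=enclosed,
    )


def sample_uniform_in_polygon(
    hr: HomeRange | MultiPolygon | Polygon,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` points uniformly inside a polygon by rejection sampling.

    Reproducible given a seeded generator; returns an ``(n, 2)`` array.
    """
    geom = hr.geometry if isinstance(hr, HomeRange) else hr
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty((0, 2))
    if geom.is_empty or geom.area <= 0:
        raise ValueError("degenerate polygon: zero area")
    rng = np.random.default_rng(rng)
    xmin, ymin, xmax, ymax = geom.bounds
    out = np.empty((n, 2))
    filled = 0
    # batches sized by the polygon's share of its bounding box
    frac = max(geom.area / ((xmax - xmin) * (ymax - ymin)), 1e-6)
    while filled < n:
        m = int((n - filled) / frac * 1.2) + 16
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = cand[shapely.contains_xy(geom, cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def clip_home_range(hr: HomeRange, extent: tuple[float, float, float, float]) -> HomeRange:
    """Clip an isopleth polygon to a raster extent (xmin, ymin, xmax, ymax).

    Kernel smoothing can push an isopleth slightly past the mapped area;
    covariates are undefined there, so the usable range is the overlap.
    """
    from shapely.geometry import box

    xmin, ymin, xmax, ymax = extent
    geom = hr.geometry.intersection(box(xmin, ymin, xmax, ymax))
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    hr.geometry = geom
    return hr


def estimate_home_range(
    locations: pd.DataFrame,
    level: float = 0.99,
    grid_resolution: float = 250.0,
    bandwidth=None,
    owner: str = "population",
) -> HomeRange:
    """Convenience: daily-subsampled fixes -> UD -> isopleth home range."""
    ud, h = estimate_kde_ud(locations, bandwidth=bandwidth, grid_resolution=grid_resolution)
    return extract_isopleth(ud, level=level, owner=owner, bandwidth=h)
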