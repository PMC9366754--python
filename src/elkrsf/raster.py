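"""Regular-grid raster surfaces: container, IO and covariate extraction.

Rasters are planar (metre-based) grids with cell-centre registration,
x increasing east and y increasing north.  Array row 0 is the NORTHERN
(top) row, matching the ESRI ASCII grid convention; ``origin_x``/
``origin_y`` give the lower-left corner of the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RasterSurface",
    "OutOfExtentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "extract_covariates",
]


class OutOfExtentError(ValueError):
    """A query point fell outside the raster extent or on a nodata cell."""


@dataclass
class RasterSurface:
    """A single-band raster over a planar extent.

    Parameters
    ----------
    values
        2-D array, shape ``(n_rows, n_cols)``; row 0 is the top (north) row.
        Nodata cells are NaN.
    origin_x, origin_y
        Coordinates (metres) of the lower-left corner of the grid.
    cell_size
        Square cell edge length in metres; must be positive.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata_flag: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must have at least one row and column")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (west→east) and y (south→north) cell-centre coords."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def _indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col); boundary points go to the lower-index cell."""
        # ceil(t) - 1 puts a point exactly on an edge into the lower-index cell
        col = np.ceil((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int) - 1
        i_bottom = np.ceil((np.asarray(y, float) - self.origin_y) / self.cell_size).astype(int) - 1
        col = np.clip(col, 0, self.n_cols - 1)
        i_bottom = np.clip(i_bottom, 0, self.n_rows - 1)
        row = self.n_rows - 1 - i_bottom
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def value_at(self, x, y, method: str = "nearest") -> np.ndarray:
        """Sample the surface at planar points.

        ``method`` is ``"nearest"`` (value of the containing cell; edge
        points resolve to the lower-index cell) or ``"bilinear"``
        (interpolation between the four surrounding cell centres, clamped
        at the outermost centres).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)[0]
            raise OutOfExtentError(
                f"point ({x[bad]:.3f}, {y[bad]:.3f}) lies outside raster extent {self.extent}"
            )
        if method == "nearest":
            row, col = self._indices(x, y)
            out = self.values[row, col]
        elif method == "bilinear":
            out = self._bilinear(x, y)
        else:
            raise ValueError(f"unknown lookup method {method!r}")
        if np.any(np.isnan(out)):
            bad = np.flatnonzero(np.isnan(out))[0]
            raise OutOfExtentError(
                f"point ({x[bad]:.3f}, {y[bad]:.3f}) falls on a nodata cell"
            )
        return out

    def _bilinear(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xs, ys = self.cell_centers()
        fx = np.clip((x - xs[0]) / self.cell_size, 0.0, self.n_cols - 1.0)
        fy = np.clip((y - ys[0]) / self.cell_size, 0.0, self.n_rows - 1.0)
        c0 = np.clip(np.floor(fx).astype(int), 0, self.n_cols - 2) if self.n_cols > 1 else np.zeros_like(fx, int)
        r0 = np.clip(np.floor(fy).astype(int), 0, self.n_rows - 2) if self.n_rows > 1 else np.zeros_like(fy, int)
        tx = fx - c0
        ty = fy - r0
        # values indexed bottom-up for interpolation
        flip = self.values[::-1, :]
        c1 = np.minimum(c0 + 1, self.n_cols - 1)
        r1 = np.minimum(r0 + 1, self.n_rows - 1)
        v00 = flip[r0, c0]
        v01 = flip[r0, c1]
        v10 = flip[r1, c0]
        v11 = flip[r1, c1]
        return (
            v00 * (1 - tx) * (1 - ty)
            + v01 * tx * (1 - ty)
            + v10 * (1 - tx) * ty
            + v11 * tx * ty
        )

    def mass(self) -> float:
        """Sum of values times cell area (density grids integrate with this)."""
        return float(np.nansum(self.values)) * self.cell_size**2


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> RasterSurface:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    if "xllcorner" in header:
        ox, oy = header["xllcorner"], header["yllcorner"]
    else:  # centre registration in the header
        ox = header["xllcenter"] - cell / 2
        oy = header["yllcenter"] - cell / 2
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return RasterSurface(values, ox, oy, cell, nodata_flag=nodata)


def write_ascii_grid(raster: RasterSurface, path: str | Path) -> None:
    path = Path(path)
    vals = np.where(np.isnan(raster.values), raster.nodata_flag, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin_x:.6f}\n")
        fh.write(f"yllcorner {raster.origin_y:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata_flag:g}\n")
        np.savetxt(fh, vals, fmt="%.8g")


_TAG_PIXEL_SCALE = 33550  # ModelPixelScaleTag
_TAG_TIEPOINT = 33922  # ModelTiepointTag


def read_geotiff(path: str | Path) -> RasterSurface:
    """Read a single-band GeoTIFF with pixel-scale + tiepoint georeferencing."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
    if values.ndim == 3:
        values = values[..., 0]
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise ValueError("only square cells are supported")
    # tiepoint maps raster (col, row) = (tie[0], tie[1]) to world (tie[3], tie[4]);
    # the conventional tiepoint is the outer top-left corner of pixel (0, 0)
    top_left_x = float(tie[3]) - float(tie[0]) * sx
    top_left_y = float(tie[4]) + float(tie[1]) * sy
    ox = top_left_x
    oy = top_left_y - values.shape[0] * sy
    return RasterSurface(values, ox, oy, sx)


def write_geotiff(raster: RasterSurface, path: str | Path) -> None:
    import tifffile

    top_left_y = raster.origin_y + raster.n_rows * raster.cell_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.origin_x, top_left_y, 0.0)),
    ]
    tifffile.imwrite(str(path), raster.values, extratags=extratags)


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------

def floored_log(raster: RasterSurface) -> RasterSurface:
    """Natural log of a positive surface, flooring at its smallest positive value.

    Predator relative-use surfaces can contain zeros; flooring at the
    smallest positive value keeps the log finite without inventing a scale.
    """
    vals = raster.values
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        raise ValueError("surface has no positive values to take a log of")
    floor = float(positive.min())
    out = np.log(np.maximum(vals, floor))
    return RasterSurface(out, raster.origin_x, raster.origin_y, raster.cell_size,
                         nodata_flag=raster.nodata_flag)


def extract_covariates(points, de: RasterSurface, lion: RasterSurface,
                       wolf: RasterSurface, method: str = "nearest"):
    """Build the (DE, ML, WF) covariate rows for a set of planar points.

    DE is sampled raw (kcal/g); the predator surfaces are floored at their
    smallest positive value and log-transformed, so ML and WF are logs of
    relative probability of predator use.

    ``points`` is an ``(n, 2)`` array or a DataFrame with ``x``/``y`` columns.
    Returns a DataFrame with columns ``x, y, de, ml, wf``.
    """
    import pandas as pd

    if hasattr(points, "columns"):
        x = np.asarray(points["x"], float)
        y = np.asarray(points["y"], float)
    else:
        pts = np.atleast_2d(np.asarray(points, float))
        x, y = pts[:, 0], pts[:, 1]
    ml_surface = floored_log(lion)
    wf_surface = floored_log(wolf)
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "de": de.value_at(x, y, method=method),
            "ml": ml_surface.value_at(x, y, method=method),
            "wf": wf_surface.value_at(x, y, method=method),
        }
    )
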