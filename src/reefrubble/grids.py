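"""Gridded bathymetry: container, ESRI ASCII I/O, bilinear sampling, cell aspect.

Depths are positive-down metres everywhere inside the package ("depth 12"
means 12 m below mean sea level). On disk, ESRI ASCII grids store elevation
(negative below sea level, matching satellite-derived bathymetry products);
the reader and writer negate at the boundary. Missing data is NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

CELL_SIZE_M = 10.0


@dataclass
class BathymetryGrid:
    """Regular bathymetry raster, row 0 at the northern edge.

    Parameters
    ----------
    depth : ndarray of shape (nrows, ncols)
        Positive-down depth in metres; NaN marks nodata.
    cell_size : float
        Cell edge length in metres (10 m for the source products this
        package targets).
    x_origin, y_origin : float
        Coordinates of the lower-left corner of the grid (map units =
        metres for synthetic grids).
    """

    depth: np.ndarray
    cell_size: float = CELL_SIZE_M
    x_origin: float = 0.0
    y_origin: float = 0.0
    _interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centres; x along columns, y along rows."""
        nrows, ncols = self.depth.shape
        x = self.x_origin + (np.arange(ncols) + 0.5) * self.cell_size
        y = self.y_origin + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return x, y

    def sample_bilinear(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of depth at map coordinates.

        Points outside the convex hull of cell centres, or with a NaN cell
        in their 2x2 neighbourhood, return NaN.
        """
        if self._interp is None:
            x, y = self.cell_centers()
            # RegularGridInterpolator wants ascending axes; rows run north->south
            self._interp = RegularGridInterpolator(
                (y[::-1], x),
                self.depth[::-1, :],
                method="linear",
                bounds_error=False,
                fill_value=np.nan,
            )
        pts = np.column_stack([np.atleast_1d(ys), np.atleast_1d(xs)])
        return self._interp(pts)


def read_esri_ascii(path: str | Path) -> BathymetryGrid:
    """Read an ESRI ASCII grid of elevations into a positive-down grid."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    data = np.loadtxt(lines[n_header:].__iter__(), dtype=float, ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {data.shape} does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    return BathymetryGrid(
        depth=-data,  # elevation on disk -> positive-down depth in memory
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
    )


def write_esri_ascii(grid: BathymetryGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a grid as ESRI ASCII elevations (negated depth)."""
    elev = -grid.depth
    elev = np.where(np.isnan(elev), nodata, elev)
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.x_origin}\n")
        fh.write(f"yllcorner {grid.y_origin}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, elev, fmt="%.6g")


def cell_aspect(grid: BathymetryGrid) -> np.ndarray:
    """Per-cell downslope aspect, degrees clockwise from north.

    Uses Horn's 3x3 finite-difference estimator on elevation (negated
    depth), the method behind the standard GIS Aspect tool. Border cells
    and flat cells (zero gradient) are NaN.
    """
    if grid.shape[0] < 3 or grid.shape[1] < 3:
        raise ValueError("grid must be at least 3x3 for aspect estimation")
    z = -grid.depth  # elevation
    c = grid.cell_size
    # Horn kernel; rows run north (index 0) to south, so the "south minus
    # north" difference is ahead-row minus behind-row.
    dzdx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * c)
    dzdy_south = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8 * c)
    with np.errstate(invalid="ignore"):
        raw = np.degrees(np.arctan2(dzdy_south, -dzdx))
        aspect = np.where(raw < 90.0, 90.0 - raw, 450.0 - raw) % 360.0
    aspect[(dzdx == 0) & (dzdy_south == 0)] = np.nan
    out = np.full(grid.shape, np.nan)
    out[1:-1, 1:-1] = aspect
    return out
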