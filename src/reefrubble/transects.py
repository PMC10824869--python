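"""Transect profile extraction, truncation, reef assignment and aspect.

A transect is a 500-m line laid across the forereef slope; its profile is
the sequence of bilinearly interpolated depths every 10 m along it. Both
ends are truncated where they rise above 2 m depth so reef crests and flats
are excluded, the transect is assigned to the nearest reef polygon within a
1000-m search radius, and its mean aspect (circular mean of cell aspects
within a 10-m buffer) is classified into N/E/S/W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point

from .grids import BathymetryGrid, cell_aspect
from .synthetic import SAMPLE_SPACING_M

TRUNCATION_DEPTH_M = 2.0
REEF_SEARCH_RADIUS_M = 1000.0
ASPECT_BUFFER_M = 10.0


@dataclass
class TransectLine:
    id: str
    start: tuple[float, float]
    end: tuple[float, float]
    reef_id: str | None = None

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("transect line must have positive length")

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    @property
    def geometry(self) -> LineString:
        return LineString([self.start, self.end])


@dataclass
class Profile:
    """One transect's ordered depth samples at fixed 10-m spacing."""

    transect_id: str
    reef_id: str | None
    distance_m: np.ndarray
    depth_m: np.ndarray
    mean_aspect_deg: float = np.nan
    aspect_class: str | None = None

    def __post_init__(self) -> None:
        self.distance_m = np.asarray(self.distance_m, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.distance_m.shape != self.depth_m.shape:
            raise ValueError("distance and depth arrays must align")
        if len(self.depth_m) >= 2:
            steps = np.diff(self.distance_m)
            if not np.allclose(steps, SAMPLE_SPACING_M):
                raise ValueError("profile spacing must be exactly 10 m")

    def __len__(self) -> int:
        return len(self.depth_m)


class EmptyProfileError(ValueError):
    """Raised when a transect yields no usable depth samples."""


def sample_profile(grid: BathymetryGrid, line: TransectLine) -> np.ndarray:
    """Raw depth sequence along a transect line at 10-m steps.

    Depths are bilinearly interpolated from the line's start; nodata cells
    and points outside the grid propagate as NaN. Raises
    :class:`EmptyProfileError` if no sample falls on valid data.
    """
    n = int(np.floor(line.length / SAMPLE_SPACING_M)) + 1
    t = np.arange(n) * SAMPLE_SPACING_M / line.length
    xs = line.start[0] + t * (line.end[0] - line.start[0])
    ys = line.start[1] + t * (line.end[1] - line.start[1])
    depths = grid.sample_bilinear(xs, ys)
    if np.all(np.isnan(depths)):
        raise EmptyProfileError(f"transect {line.id} lies wholly outside valid data")
    return depths


def truncate_profile(depths: np.ndarray) -> tuple[int, int]:
    """Indices (start, stop) after stripping shallow (and missing) ends.

    Removes every leading and trailing point with depth <= 2 m or NaN;
    interior points are never touched. Returns a half-open slice; an empty
    slice means the profile was fully truncated.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth sequence")
    bad = np.isnan(depths) | (depths <= TRUNCATION_DEPTH_M)
    start, stop = 0, depths.size
    while start < stop and bad[start]:
        start += 1
    while stop > start and bad[stop - 1]:
        stop -= 1
    return start, stop


def assign_reef(
    line: TransectLine,
    reef_polygons: dict[str, "shapely.geometry.base.BaseGeometry"],
    search_radius_m: float = REEF_SEARCH_RADIUS_M,
) -> str | None:
    """Nearest reef polygon id within the search radius, else None.

    Distance is to the polygon boundary or interior (0 if the transect
    intersects the polygon). Ties broken by reef id for determinism.
    """
    geom = line.geometry
    best: tuple[float, str] | None = None
    for reef_id in sorted(reef_polygons):
        d = geom.distance(reef_polygons[reef_id])
        if d <= search_radius_m and (best is None or d < best[0]):
            best = (d, reef_id)
    return best[1] if best else None


def mean_aspect(aspects_deg: np.ndarray) -> float:
    """Circular (vector) mean of aspect angles in degrees.

    Computes [360 + atan2(s, c) * 180/pi] mod 360 where s and c are the
    means of the sines and cosines of the aspects. NaN entries (flat
    cells) are ignored; all-NaN input returns NaN.
    """
    a = np.radians(np.asarray(aspects_deg, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    return float((360.0 + np.degrees(np.arctan2(s, c))) % 360.0)


def classify_aspect(mean_aspect_deg: float) -> str | None:
    """Map an aspect angle to {N, E, S, W} with 45-degree-centred classes.

    N = [315, 360) v [0, 45); E = [45, 135); S = [135, 225); W = [225, 315).
    Undefined (NaN) aspect has no class.
    """
    if np.isnan(mean_aspect_deg):
        return None
    a = mean_aspect_deg % 360.0
    if a < 45.0 or a >= 315.0:
        return "N"
    if a < 135.0:
        return "E"
    if a < 225.0:
        return "S"
    return "W"


def _cells_near_line(grid: BathymetryGrid, line: TransectLine, buffer_m: float) -> np.ndarray:
    """Boolean mask of cells whose centres lie within buffer_m of the line."""
    x, y = grid.cell_centers()
    X, Y = np.meshgrid(x, y)
    p1 = np.asarray(line.start, dtype=float)
    d = np.asarray(line.end, dtype=float) - p1
    L2 = d @ d
    t = np.clip(((X - p1[0]) * d[0] + (Y - p1[1]) * d[1]) / L2, 0.0, 1.0)
    dist = np.hypot(X - (p1[0] + t * d[0]), Y - (p1[1] + t * d[1]))
    return dist <= buffer_m


def transect_mean_aspect(
    grid: BathymetryGrid,
    line: TransectLine,
    aspects: np.ndarray | None = None,
    buffer_m: float = ASPECT_BUFFER_M,
) -> float:
    """Zonal circular-mean aspect of the cells within 10 m of a transect."""
    if aspects is None:
        aspects = cell_aspect(grid)
    mask = _cells_near_line(grid, line, buffer_m)
    return mean_aspect(aspects[mask])


def extract_profiles(
    grid: BathymetryGrid,
    lines: list[TransectLine],
    reef_polygons: dict | None = None,
    compute_aspect: bool = True,
) -> list[Profile]:
    """Full per-transect extraction: sample, truncate, assign, orient.

    Transects that are fully truncated (entirely shallower than 2 m) or
    wholly outside valid data are dropped. Interior NaNs are retained and
    must be handled by downstream cleaning.
    """
    aspects = cell_aspect(grid) if compute_aspect else None
    profiles: list[Profile] = []
    for line in lines:
        try:
            raw = sample_profile(grid, line)
        except EmptyProfileError:
            continue
        start, stop = truncate_profile(raw)
        if stop - start < 2:
            continue
        reef_id = line.reef_id
        if reef_id is None and reef_polygons:
            reef_id = assign_reef(line, reef_polygons)
        ma = transect_mean_aspect(grid, line, aspects) if compute_aspect else np.nan
        profiles.append(
            Profile(
                transect_id=line.id,
                reef_id=reef_id,
                distance_m=np.arange(stop - start) * SAMPLE_SPACING_M,
                depth_m=raw[start:stop],
                mean_aspect_deg=ma,
                aspect_class=classify_aspect(ma),
            )
        )
    return profiles
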