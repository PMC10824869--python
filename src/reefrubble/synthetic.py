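"""Synthetic inputs: 1-D terrain profiles, small reef bathymetry grids,
and beta-mixture proportion datasets.

Every generator is a pure function of its spec (including the seed), so the
whole downstream pipeline is testable without external bathymetry products.
Generated depths follow the package-wide positive-down convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .grids import BathymetryGrid, CELL_SIZE_M

SAMPLE_SPACING_M = 10.0

SEGMENT_KINDS = ("flat", "ramp", "depression", "dropoff", "high")


@dataclass(frozen=True)
class Segment:
    """One building block of a synthetic depth profile.

    kind:
        flat       — constant depth
        ramp       — deepens linearly by ``relief_m`` over ``length_m``
        dropoff    — alias of ramp, conventionally with relief >= 5 m
        depression — V-shaped dip of ``relief_m`` returning to the entry depth
        high       — inverted V rising (shallowing) by ``relief_m``
    """

    kind: str
    length_m: float
    relief_m: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length_m <= 0 or self.length_m % SAMPLE_SPACING_M != 0:
            raise ValueError("length_m must be a positive multiple of 10 m")
        if self.relief_m < 0:
            raise ValueError("relief_m must be non-negative")


@dataclass(frozen=True)
class TerrainSpec:
    segments: tuple[Segment, ...]
    base_depth_m: float = 12.0
    noise_sd_m: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("TerrainSpec needs at least one segment")
        if self.base_depth_m <= 0:
            raise ValueError("base_depth_m must be positive (positive-down)")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be non-negative")


def _segment_offsets(seg: Segment, start_depth: float) -> np.ndarray:
    """Depths of the samples a segment appends (excluding its entry point)."""
    n = int(round(seg.length_m / SAMPLE_SPACING_M))
    if seg.kind == "flat":
        return np.full(n, start_depth)
    if seg.kind in ("ramp", "dropoff"):
        return start_depth + seg.relief_m * np.arange(1, n + 1) / n
    # V shapes: deepest/shallowest point placed exactly on a sample
    n_down = max(1, math.ceil(n / 2)) if n > 1 else 1
    n_up = n - n_down
    sign = 1.0 if seg.kind == "depression" else -1.0
    leg1 = start_depth + sign * seg.relief_m * np.arange(1, n_down + 1) / n_down
    if n_up > 0:
        leg2 = start_depth + sign * seg.relief_m * (1 - np.arange(1, n_up + 1) / n_up)
        return np.concatenate([leg1, leg2])
    return leg1


def make_profile(spec: TerrainSpec) -> pd.DataFrame:
    """Realise a terrain spec as a profile table.

    Returns a DataFrame with columns ``distance_m`` and ``depth_m`` at exact
    10-m spacing, beginning with the base-depth entry point. Each segment
    realises its declared relief exactly before noise is added.
    """
    depths = [np.array([spec.base_depth_m])]
    current = spec.base_depth_m
    for seg in spec.segments:
        vals = _segment_offsets(seg, current)
        depths.append(vals)
        current = vals[-1]
    depth = np.concatenate(depths)
    if spec.noise_sd_m > 0:
        rng = np.random.default_rng(spec.seed)
        depth = depth + rng.normal(0.0, spec.noise_sd_m, size=depth.size)
        depth = np.clip(depth, 0.05, None)  # depths stay positive
    distance = np.arange(depth.size) * SAMPLE_SPACING_M
    return pd.DataFrame({"distance_m": distance, "depth_m": depth})


@dataclass(frozen=True)
class ReefGridSpec:
    """Small 2-D reef surface for transect sampling and aspect tests."""

    shape: tuple[int, int] = (80, 80)
    geometry: str = "annular_platform"
    crest_depth_m: float = 1.5
    slope_base_depth_m: float = 25.0
    slope_width_m: float = 150.0
    noise_sd_m: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("annular_platform", "ribbon"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not self.crest_depth_m < self.slope_base_depth_m:
            raise ValueError("crest must be shallower than the slope base")
        if self.crest_depth_m <= 0:
            raise ValueError("depths are positive-down and must be > 0")
        if self.slope_width_m <= 0:
            raise ValueError("slope_width_m must be positive")
        rows, cols = self.shape
        need = 2 * (self.slope_width_m / CELL_SIZE_M + 3)
        if rows < need or cols < need:
            raise ValueError("grid too small to contain the reef geometry")


def make_reef_grid(spec: ReefGridSpec) -> BathymetryGrid:
    """Build a reef bathymetry grid with a shallow crest and deepening slope.

    annular_platform: a flat platform at crest depth whose rim ramps
    linearly down to the slope base over ``slope_width_m`` (radially
    monotone non-decreasing depth, pre-noise).
    ribbon: a north-south crest line with linear east and west flanks, so
    the west flank faces west (aspect ~270 deg) and the east flank east.
    """
    rows, cols = spec.shape
    cell = CELL_SIZE_M
    xi = (np.arange(cols) + 0.5) * cell
    yi = (np.arange(rows) + 0.5) * cell
    X, Y = np.meshgrid(xi, yi)
    if spec.geometry == "annular_platform":
        cx, cy = cols * cell / 2, rows * cell / 2
        r = np.hypot(X - cx, Y - cy)
        extent = min(cols, rows) * cell / 2
        r_platform = extent - spec.slope_width_m - 2 * cell
        ramp = np.clip((r - r_platform) / spec.slope_width_m, 0.0, 1.0)
    else:  # ribbon
        x_crest = cols * cell / 2
        ramp = np.clip(np.abs(X - x_crest) / spec.slope_width_m, 0.0, 1.0)
    depth = spec.crest_depth_m + ramp * (spec.slope_base_depth_m - spec.crest_depth_m)
    if spec.noise_sd_m > 0:
        rng = np.random.default_rng(spec.seed)
        depth = np.clip(depth + rng.normal(0, spec.noise_sd_m, depth.shape), 0.05, None)
    return BathymetryGrid(depth=depth, cell_size=cell)


def transects_along_polyline(
    vertices: np.ndarray,
    spacing_m: float = 500.0,
    length_m: float = 500.0,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Transect endpoint pairs as normals to an axis polyline.

    Stations are placed every ``spacing_m`` of arc length along the
    polyline; at each station a segment of ``length_m`` centred on the axis
    is laid out perpendicular to the local direction.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("polyline needs at least two vertices")
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    stations = np.arange(0.0, cum[-1] + 1e-9, spacing_m)
    out = []
    for s in stations:
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seglen) - 1)
        t = (s - cum[i]) / seglen[i] if seglen[i] > 0 else 0.0
        p = v[i] + t * seg[i]
        d = seg[i] / seglen[i]
        normal = np.array([-d[1], d[0]])
        half = normal * length_m / 2
        out.append((tuple(p - half), tuple(p + half)))
    return out


def annular_axis(spec: ReefGridSpec, n_vertices: int = 64) -> np.ndarray:
    """Closed polyline tracing the mid-slope ring of an annular platform."""
    rows, cols = spec.shape
    cell = CELL_SIZE_M
    cx, cy = cols * cell / 2, rows * cell / 2
    extent = min(cols, rows) * cell / 2
    r_mid = extent - spec.slope_width_m / 2 - 2 * cell
    theta = np.linspace(0, 2 * np.pi, n_vertices + 1)
    return np.column_stack([cx + r_mid * np.cos(theta), cy + r_mid * np.sin(theta)])


@dataclass(frozen=True)
class MixtureSimSpec:
    """Two-component beta-regression mixture simulation.

    Coefficients are on the logit scale over the design
    (intercept, deep, E, S, W) with references shallow and N.
    """

    n_obs: int = 5000
    mixing_weight: float = 0.3
    coef_1: tuple[float, ...] = (-2.0, 0.0, 0.0, 0.0, 0.0)
    coef_2: tuple[float, ...] = (1.0, 0.3, -0.2, -0.3, 0.1)
    precision_1: float = 20.0
    precision_2: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mixing_weight < 1:
            # pi = 1 is handled as a documented degenerate case for testing
            if self.mixing_weight != 1.0:
                raise ValueError("mixing_weight must be in (0, 1] ")
        if self.precision_1 <= 0 or self.precision_2 <= 0:
            raise ValueError("precisions must be positive")
        if len(self.coef_1) != 5 or len(self.coef_2) != 5:
            raise ValueError("coefficient vectors must have 5 entries")
        if self.n_obs < 1:
            raise ValueError("n_obs must be positive")


def simulate_mixture(spec: MixtureSimSpec) -> pd.DataFrame:
    """Draw proportions from a two-component beta regression mixture.

    Each observation belongs to component 1 with probability
    ``mixing_weight``; its response is Beta(mu * phi, (1 - mu) * phi) with
    logit(mu) = x' beta_k over a balanced random depth/aspect design.
    Returns columns proportion, depth_class, aspect_class, true_component.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_obs
    depth_class = rng.choice(["shallow", "deep"], size=n)
    aspect_class = rng.choice(["N", "E", "S", "W"], size=n)
    X = np.column_stack(
        [
            np.ones(n),
            depth_class == "deep",
            aspect_class == "E",
            aspect_class == "S",
            aspect_class == "W",
        ]
    ).astype(float)
    comp = np.where(rng.random(n) < spec.mixing_weight, 1, 2)
    beta = {1: np.asarray(spec.coef_1), 2: np.asarray(spec.coef_2)}
    phi = {1: spec.precision_1, 2: spec.precision_2}
    y = np.empty(n)
    for k in (1, 2):
        mask = comp == k
        mu = expit(X[mask] @ beta[k])
        y[mask] = rng.beta(mu * phi[k], (1 - mu) * phi[k])
    # guard against floating-point exact 0/1 from the beta sampler
    eps = np.finfo(float).tiny
    y = np.clip(y, eps, 1 - eps)
    return pd.DataFrame(
        {
            "proportion": y,
            "depth_class": depth_class,
            "aspect_class": aspect_class,
            "true_component": comp,
        }
    )


def random_terrain_spec(rng: np.random.Generator, max_segments: int = 6) -> TerrainSpec:
    """Random terrain spec for property tests and oracle cross-checks."""
    n_seg = int(rng.integers(1, max_segments + 1))
    segs = []
    for _ in range(n_seg):
        kind = str(rng.choice(SEGMENT_KINDS))
        length = float(rng.integers(2, 12) * 10)
        relief = 0.0 if kind == "flat" else float(np.round(rng.uniform(0.1, 7.0), 2))
        segs.append(Segment(kind, length, relief))
    return TerrainSpec(
        segments=tuple(segs),
        base_depth_m=float(np.round(rng.uniform(4.0, 20.0), 2)),
        noise_sd_m=float(np.round(rng.uniform(0.0, 0.3), 3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
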