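"""The rubble-accumulation decision tree.

For every 10-m focal point on a transect profile a moving window (50 m to
each side in the base case) is examined and the point is flagged as able to
accumulate coral rubble when:

1. the depth range (max - min) inside the window is below the roll
   threshold — otherwise the point is on or near a steep slope and rubble
   rolls away;
2. the point is not a local topographic high — strictly shallower than
   every point on both sides of the window;
3. and either the depression rule holds — the shallowest point on EACH
   side of the focal point sits at least ``rubble_height_m`` above it, so a
   rubble layer of that thickness fits below the flanks — or the flat rule
   holds — the window's depth range is within ``flat_depth_change_m``.

Depths are positive-down metres. Sections shallower than 10 m are
"shallow", the rest "deep"; potential rubble cover is reported overall and
per section.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import SAMPLE_SPACING_M

SHALLOW_DEEP_SPLIT_M = 10.0

PARAM_NAMES = (
    "moving_window_m",
    "rubble_height_m",
    "roll_depth_range_m",
    "flat_depth_change_m",
)


@dataclass(frozen=True)
class RubbleParams:
    """The four tunable parameters of the accumulation algorithm.

    moving_window_m
        Spatial scale over which local relief is evaluated to each side of
        the focal point (base 50 m = 5 samples at 10-m spacing).
    rubble_height_m
        Minimum thickness of accumulated rubble considered problematic for
        coral recovery (base 0.5 m); a depression must be at least this
        deep relative to both flanks to trap a problematic layer.
    roll_depth_range_m
        Depth range within the window at or above which the point is on or
        near a steep slope and rubble rolls off (base 5 m).
    flat_depth_change_m
        Maximum depth range within the window for the surface to count as
        flat (base 0.5 m).
    """

    moving_window_m: float = 50.0
    rubble_height_m: float = 0.5
    roll_depth_range_m: float = 5.0
    flat_depth_change_m: float = 0.5

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.flat_depth_change_m < self.roll_depth_range_m:
            raise ValueError("flat_depth_change_m must be below roll_depth_range_m")

    def half_window_samples(self, spacing_m: float = SAMPLE_SPACING_M) -> int:
        """Window half-width in samples; non-multiples of the spacing round
        to the nearest sample (60 m -> 6, 40 m -> 4)."""
        return max(1, int(round(self.moving_window_m / spacing_m)))

    def scaled(self, name: str, factor: float) -> "RubbleParams":
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass
class TransectResult:
    """Per-point accumulation flags and cover summaries for one transect."""

    transect_id: str
    reef_id: str | None
    accumulates: np.ndarray  # bool per point
    section: np.ndarray  # "shallow" / "deep" per point
    depth_m: np.ndarray
    filled_depth_m: np.ndarray  # depth - rubble_height at flagged points
    cover_pct_total: float
    cover_pct_shallow: float  # NaN if no shallow points
    cover_pct_deep: float


def window_indices(
    profile_length: int,
    focal_index: int,
    moving_window_m: float = 50.0,
    spacing_m: float = SAMPLE_SPACING_M,
) -> tuple[int, int]:
    """Half-open index range of the moving window, truncated at the ends."""
    if not 0 <= focal_index < profile_length:
        raise IndexError("focal index outside profile")
    k = max(1, int(round(moving_window_m / spacing_m)))
    return max(0, focal_index - k), min(profile_length, focal_index + k + 1)


def evaluate_focal_point(
    depths: np.ndarray,
    focal_index: int,
    params: RubbleParams = RubbleParams(),
    spacing_m: float = SAMPLE_SPACING_M,
) -> bool:
    """Decision tree at a single focal point; True = rubble accumulates."""
    depths = np.asarray(depths, dtype=float)
    lo, hi = window_indices(len(depths), focal_index, params.moving_window_m, spacing_m)
    window = depths[lo:hi]
    focal = depths[focal_index]
    depth_range = float(np.max(window) - np.min(window))
    if depth_range >= params.roll_depth_range_m:
        return False  # steep slope or proximal to one: rubble rolls away
    left = depths[lo:focal_index]
    right = depths[focal_index + 1:hi]
    both_sides = left.size > 0 and right.size > 0
    if both_sides and focal < left.min() and focal < right.min():
        return False  # local topographic high
    depression = (
        both_sides
        and focal - left.min() >= params.rubble_height_m
        and focal - right.min() >= params.rubble_height_m
    )
    flat = depth_range <= params.flat_depth_change_m
    return depression or flat


def _windowed_extrema(depths: np.ndarray, k: int) -> tuple[np.ndarray, ...]:
    """Vectorised per-point window max/min and per-side minima.

    Pads with NaN at the ends so edge windows truncate naturally; an empty
    side yields NaN.
    """
    n = depths.size
    padded = np.concatenate([np.full(k, np.nan), depths, np.full(k, np.nan)])
    win = np.lib.stride_tricks.sliding_window_view(padded, 2 * k + 1)
    with np.errstate(all="ignore"):
        wmax = np.nanmax(win, axis=1)
        wmin = np.nanmin(win, axis=1)
        left_min = np.full(n, np.nan)
        right_min = np.full(n, np.nan)
        left = win[:, :k]
        right = win[:, k + 1:]
        has_left = ~np.all(np.isnan(left), axis=1)
        has_right = ~np.all(np.isnan(right), axis=1)
        left_min[has_left] = np.nanmin(left[has_left], axis=1)
        right_min[has_right] = np.nanmin(right[has_right], axis=1)
    return wmax, wmin, left_min, right_min


def evaluate_profile_flags(
    depths: np.ndarray,
    params: RubbleParams = RubbleParams(),
    spacing_m: float = SAMPLE_SPACING_M,
) -> np.ndarray:
    """Vectorised accumulation flags for every point of a profile."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty profile")
    if np.any(np.isnan(depths)):
        raise ValueError("profile contains missing depths; clean it first")
    k = params.half_window_samples(spacing_m)
    wmax, wmin, left_min, right_min = _windowed_extrema(depths, k)
    depth_range = wmax - wmin
    rolls = depth_range >= params.roll_depth_range_m
    both = ~np.isnan(left_min) & ~np.isnan(right_min)
    local_high = both & (depths < left_min) & (depths < right_min)
    depression = (
        both
        & (depths - left_min >= params.rubble_height_m)
        & (depths - right_min >= params.rubble_height_m)
    )
    flat = depth_range <= params.flat_depth_change_m
    return ~rolls & ~local_high & (depression | flat)


def evaluate_transect(
    profile,
    params: RubbleParams = RubbleParams(),
    spacing_m: float = SAMPLE_SPACING_M,
) -> TransectResult:
    """Flag every point of a profile and summarise potential rubble cover.

    ``profile`` is a :class:`~reefrubble.transects.Profile` (or anything
    with transect_id, reef_id and depth_m). Cover percentages are
    100 * flagged / n over all points and within the shallow (< 10 m) and
    deep sections; a section with no points has NaN cover.
    """
    depths = np.asarray(profile.depth_m, dtype=float)
    flags = evaluate_profile_flags(depths, params, spacing_m)
    shallow = depths < SHALLOW_DEEP_SPLIT_M
    section = np.where(shallow, "shallow", "deep")

    def _cover(mask: np.ndarray) -> float:
        return 100.0 * flags[mask].sum() / mask.sum() if mask.any() else float("nan")

    filled = np.where(flags, depths - params.rubble_height_m, depths)
    return TransectResult(
        transect_id=profile.transect_id,
        reef_id=profile.reef_id,
        accumulates=flags,
        section=section,
        depth_m=depths,
        filled_depth_m=filled,
        cover_pct_total=100.0 * flags.sum() / flags.size,
        cover_pct_shallow=_cover(shallow),
        cover_pct_deep=_cover(~shallow),
    )
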