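"""Independent reference implementations used only to cross-check the package.

These are deliberately naive (pure-Python loops over lists, no shared code
with the package internals) so that agreement with the optimised
implementations is meaningful.
"""

from __future__ import annotations

import math


def naive_rubble_flags(
    depths,
    moving_window_m=50.0,
    rubble_height_m=0.5,
    roll_depth_range_m=5.0,
    flat_depth_change_m=0.5,
    spacing_m=10.0,
):
    """Per-point accumulation decision, re-derived step by step.

    For each focal point: gather the window (half-width rounded to the
    sampling lattice, truncated at the ends); exclude if the window's depth
    range reaches the roll threshold; exclude a local high (strictly
    shallower than everything on both sides); flag if the shallowest point
    on each side sits at least the rubble height above the focal depth
    (depression) or the window range is within the flat threshold.
    """
    depths = [float(d) for d in depths]
    n = len(depths)
    k = max(1, round(moving_window_m / spacing_m))
    flags = []
    for i in range(n):
        lo = max(0, i - k)
        hi = min(n, i + k + 1)
        window = depths[lo:hi]
        rng = max(window) - min(window)
        if rng >= roll_depth_range_m:
            flags.append(False)
            continue
        left = depths[lo:i]
        right = depths[i + 1:hi]
        if left and right and depths[i] < min(left) and depths[i] < min(right):
            flags.append(False)
            continue
        depression = (
            bool(left)
            and bool(right)
            and depths[i] - min(left) >= rubble_height_m
            and depths[i] - min(right) >= rubble_height_m
        )
        flat = rng <= flat_depth_change_m
        flags.append(depression or flat)
    return flags


def naive_circular_mean(angles_deg):
    """Unit-vector mean of angles, summed term by term."""
    s = sum(math.sin(math.radians(a)) for a in angles_deg) / len(angles_deg)
    c = sum(math.cos(math.radians(a)) for a in angles_deg) / len(angles_deg)
    return (360.0 + math.degrees(math.atan2(s, c))) % 360.0


def naive_exceedance(covers, threshold):
    """Count of covers strictly greater than a threshold."""
    return sum(1 for c in covers if c > threshold)
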