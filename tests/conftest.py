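import numpy as np
import pytest

import reefrubble as rr
from reefrubble.synthetic import random_terrain_spec


@pytest.fixture(scope="session")
def random_profiles():
    """200 random synthetic terrain profiles shared by property suites."""
    rng = np.random.default_rng(20240)
    out = []
    for _ in range(200):
        spec = random_terrain_spec(rng)
        out.append(rr.make_profile(spec)["depth_m"].to_numpy())
    return out


@pytest.fixture(scope="session")
def demo_profiles_small():
    """A small synthetic multi-reef set (fast, deterministic)."""
    from reefrubble.io import demo_profiles

    return demo_profiles(n_reefs=6, seed=7)


def make_profile_obj(depths, transect_id="t0", reef_id="r0"):
    depths = np.asarray(depths, dtype=float)
    return rr.Profile(
        transect_id=transect_id,
        reef_id=reef_id,
        distance_m=np.arange(depths.size) * 10.0,
        depth_m=depths,
    )
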