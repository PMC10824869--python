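"""One-at-a-time parameter sensitivity: identity, arithmetic, rankings."""

import numpy as np
import pandas as pd
import pytest

import reefrubble as rr
from reefrubble.sensitivity import OATResult
from conftest import make_profile_obj


@pytest.fixture(scope="module")
def mixed_profiles():
    """Profiles over several reefs with varied terrain, some with drop-offs."""
    rng = np.random.default_rng(41)
    profiles = []
    for r in range(8):
        for t in range(6):
            segs = [rr.Segment("flat", 100.0)]
            if (r + t) % 3 == 0:
                segs.append(rr.Segment("dropoff", 50.0, float(rng.uniform(4, 7))))
            if (r + t) % 2 == 0:
                segs.append(rr.Segment("depression", 40.0, float(rng.uniform(0.4, 1.5))))
            segs.append(rr.Segment("ramp", 100.0, float(rng.uniform(0.2, 3.0))))
            depths = rr.make_profile(
                rr.TerrainSpec(tuple(segs), base_depth_m=float(rng.uniform(5, 15)),
                               noise_sd_m=0.1, seed=int(rng.integers(1 << 30)))
            )["depth_m"].to_numpy()
            profiles.append(make_profile_obj(depths, f"R{r}T{t}", f"R{r}"))
    return profiles


class TestRunOAT:
    def test_zero_perturbation_reproduces_base(self, mixed_profiles):
        """A parameter scaled by 1.0 must give bit-identical pipeline output."""
        base = rr.RubbleParams()
        same = base.scaled("moving_window_m", 1.0)
        results_a = [rr.evaluate_transect(p, base) for p in mixed_profiles]
        results_b = [rr.evaluate_transect(p, same) for p in mixed_profiles]
        for a, b in zip(results_a, results_b):
            np.testing.assert_array_equal(a.accumulates, b.accumulates)
            assert a.cover_pct_total == b.cover_pct_total

    def test_eight_non_base_scenarios(self, mixed_profiles):
        oat = rr.run_oat(mixed_profiles, thresholds=(30, 40))
        runs = oat.counts.groupby(["parameter", "scenario"]).ngroups
        assert runs == 8

    def test_wider_window_cannot_increase_counts_near_dropoffs(self):
        # isolated drop-offs: widening the window exposes more points to
        # >=5-m relief so problematic-reef counts cannot rise
        profiles = []
        for r in range(6):
            segs = (rr.Segment("flat", 120.0), rr.Segment("dropoff", 40.0, 6.0),
                    rr.Segment("flat", 120.0))
            depths = rr.make_profile(
                rr.TerrainSpec(segs, base_depth_m=8.0 + r)
            )["depth_m"].to_numpy()
            profiles.append(make_profile_obj(depths, f"R{r}T0", f"R{r}"))
        oat = rr.run_oat(profiles, thresholds=(30,))
        base_n = oat.base_counts["n_reefs"].iloc[0]
        wide = oat.counts[
            (oat.counts["parameter"] == "moving_window_m")
            & (oat.counts["scenario"] == "+20%")
        ]["n_reefs"].iloc[0]
        assert wide <= base_n

    def test_determinism(self, mixed_profiles):
        a = rr.run_oat(mixed_profiles, thresholds=(30,))
        b = rr.run_oat(mixed_profiles, thresholds=(30,))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.rank_changes, b.rank_changes)


def fabricate_oat(base_counts, scenario_counts, rank_rows=None):
    base = pd.DataFrame(
        [{"parameter": "all", "scenario": "base", "threshold": t, "n_reefs": n}
         for t, n in base_counts.items()]
    )
    counts = pd.DataFrame(scenario_counts)
    ranks = pd.DataFrame(rank_rows or [])
    return OATResult(counts=counts, rank_changes=ranks, base_counts=base)


class TestCountSensitivity:
    def test_single_scenario_percentage(self):
        # 336 -> 235 under one scenario: 100*|235-336|/336 = 30.06%
        oat = fabricate_oat(
            {30: 336},
            [{"parameter": "moving_window_m", "scenario": "+20%",
              "threshold": 30, "n_reefs": 235}],
        )
        assert rr.count_sensitivity(oat, "moving_window_m") == pytest.approx(
            100 * 101 / 336, abs=0.005
        )

    def test_no_change_is_zero(self):
        oat = fabricate_oat(
            {30: 10},
            [{"parameter": "rubble_height_m", "scenario": "-20%",
              "threshold": 30, "n_reefs": 10}],
        )
        assert rr.count_sensitivity(oat, "rubble_height_m") == 0.0

    def test_mean_over_thresholds_and_perturbations(self):
        oat = fabricate_oat(
            {30: 100, 40: 50, 50: 10},
            [
                {"parameter": "p", "scenario": "-20%", "threshold": 30, "n_reefs": 120},
                {"parameter": "p", "scenario": "+20%", "threshold": 30, "n_reefs": 90},
                {"parameter": "p", "scenario": "-20%", "threshold": 40, "n_reefs": 60},
                {"parameter": "p", "scenario": "+20%", "threshold": 40, "n_reefs": 40},
                {"parameter": "p", "scenario": "-20%", "threshold": 50, "n_reefs": 10},
                {"parameter": "p", "scenario": "+20%", "threshold": 50, "n_reefs": 5},
            ],
        )
        # hand-computed: (20 + 10 + 20 + 20 + 0 + 50) / 6
        assert rr.count_sensitivity(oat, "p") == pytest.approx(120 / 6)

    def test_zero_base_threshold_modes(self):
        oat = fabricate_oat(
            {30: 10, 90: 0},
            [
                {"parameter": "p", "scenario": "+20%", "threshold": 30, "n_reefs": 5},
                {"parameter": "p", "scenario": "+20%", "threshold": 90, "n_reefs": 0},
            ],
        )
        assert rr.count_sensitivity(oat, "p") == pytest.approx(50.0)  # excluded
        assert rr.count_sensitivity(oat, "p", include_zero_base=True) == pytest.approx(25.0)

    def test_all_zero_base_undefined(self):
        oat = fabricate_oat(
            {30: 0},
            [{"parameter": "p", "scenario": "+20%", "threshold": 30, "n_reefs": 3}],
        )
        assert np.isnan(rr.count_sensitivity(oat, "p"))

    def test_scale_free_in_reef_count(self):
        # doubling every count leaves the percentage change unchanged
        oat1 = fabricate_oat(
            {30: 50},
            [{"parameter": "p", "scenario": "+20%", "threshold": 30, "n_reefs": 40}],
        )
        oat2 = fabricate_oat(
            {30: 100},
            [{"parameter": "p", "scenario": "+20%", "threshold": 30, "n_reefs": 80}],
        )
        assert rr.count_sensitivity(oat1, "p") == rr.count_sensitivity(oat2, "p")


class TestRankingSensitivity:
    def test_identical_rankings_zero(self):
        rows = [
            {"parameter": "p", "scenario": "+20%", "threshold": 30,
             "reef_id": f"R{i}", "rank_base": i + 1, "rank_scenario": i + 1,
             "abs_change": 0}
            for i in range(10)
        ]
        oat = fabricate_oat({30: 5}, [], rows)
        mean, se = rr.ranking_sensitivity(oat, "p")
        assert mean == 0.0

    def test_single_moved_reef_mean(self):
        # rank 1 -> 5 for one of ten reefs: mean |change| = 4/10
        rows = [
            {"parameter": "p", "scenario": "+20%", "threshold": 30,
             "reef_id": f"R{i}", "rank_base": i + 1,
             "rank_scenario": 5 if i == 0 else i + 1,
             "abs_change": 4 if i == 0 else 0}
            for i in range(10)
        ]
        oat = fabricate_oat({30: 5}, [], rows)
        mean, _ = rr.ranking_sensitivity(oat, "p")
        assert mean == pytest.approx(0.4)

    def test_random_permutation_matches_brute_force(self):
        rng = np.random.default_rng(43)
        rows = []
        for t in (30, 40, 50):
            perm = rng.permutation(10) + 1
            for i in range(10):
                rows.append(
                    {"parameter": "p", "scenario": "-20%", "threshold": t,
                     "reef_id": f"R{i}", "rank_base": i + 1,
                     "rank_scenario": int(perm[i]),
                     "abs_change": abs(i + 1 - int(perm[i]))}
                )
        oat = fabricate_oat({30: 5, 40: 5, 50: 5}, [], rows)
        mean, se = rr.ranking_sensitivity(oat, "p")
        df = pd.DataFrame(rows)
        per_t = df.groupby("threshold")["abs_change"].mean()
        assert mean == pytest.approx(per_t.mean())
        assert se == pytest.approx(per_t.std(ddof=1) / np.sqrt(3))


class TestRankParameters:
    def _full_oat(self, count_map):
        counts, ranks = [], []
        base = {30: 100}
        for name, n in count_map.items():
            counts.append({"parameter": name, "scenario": "+20%",
                           "threshold": 30, "n_reefs": n})
            ranks.append({"parameter": name, "scenario": "+20%", "threshold": 30,
                          "reef_id": "R0", "rank_base": 1, "rank_scenario": 1,
                          "abs_change": 0})
        return fabricate_oat(base, counts, ranks)

    def test_constructed_ordering_recovered(self):
        oat = self._full_oat(
            {"moving_window_m": 40, "flat_depth_change_m": 70,
             "rubble_height_m": 85, "roll_depth_range_m": 95}
        )
        ranking = rr.rank_parameters(oat)
        assert list(ranking["parameter"]) == [
            "moving_window_m", "flat_depth_change_m",
            "rubble_height_m", "roll_depth_range_m",
        ]
        assert list(ranking["sensitivity_rank"]) == [1, 2, 3, 4]

    def test_all_equal_breaks_ties_alphabetically(self):
        oat = self._full_oat({n: 50 for n in rr.core.PARAM_NAMES})
        ranking = rr.rank_parameters(oat)
        assert list(ranking["parameter"]) == sorted(rr.core.PARAM_NAMES)
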