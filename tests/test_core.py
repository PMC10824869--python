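"""The moving-window rubble-accumulation decision tree."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reefrubble as rr
from conftest import make_profile_obj
from _oracles import naive_rubble_flags

BASE = rr.RubbleParams()


class TestWindowIndices:
    def test_base_window_five_samples_each_side(self):
        assert rr.window_indices(51, 25, 50.0) == (20, 31)

    def test_left_truncation_at_profile_start(self):
        assert rr.window_indices(51, 0, 50.0) == (0, 6)

    def test_small_window_one_sample_each_side(self):
        assert rr.window_indices(51, 25, 10.0) == (24, 27)

    def test_nearest_sample_rounding(self):
        # +/-20% scaling of the 50-m base: 60 m -> 6 samples, 40 m -> 4
        assert rr.window_indices(101, 50, 60.0) == (44, 57)
        assert rr.window_indices(101, 50, 40.0) == (46, 55)

    def test_invalid_focal_rejected(self):
        with pytest.raises(IndexError):
            rr.window_indices(10, 10, 50.0)


class TestEvaluateFocalPoint:
    def test_uniform_profile_interior_accumulates(self):
        depths = np.full(51, 12.0)
        assert rr.evaluate_focal_point(depths, 25, BASE)

    def test_steep_relief_rolls_away(self):
        depths = np.concatenate([np.full(10, 8.0), np.full(10, 14.0)])
        assert not rr.evaluate_focal_point(depths, 9, BASE)  # 6-m relief in window

    def test_v_depression_accumulates(self):
        # focal 13 m, shallowest flank 12 m each side, window relief 1 m
        depths = np.array([12.0, 12.2, 12.5, 13.0, 12.5, 12.2, 12.0])
        assert rr.evaluate_focal_point(depths, 3, BASE)

    def test_shallow_indentation_not_problematic(self):
        # dip of 0.3 m < rubble height: not a trap, and relief 0.3 <= flat
        depths = np.array([12.0, 12.0, 12.3, 12.0, 12.0])
        assert rr.evaluate_focal_point(depths, 2, BASE)  # flat rule still fires
        tall = rr.RubbleParams(flat_depth_change_m=0.2, rubble_height_m=0.5)
        assert not rr.evaluate_focal_point(depths, 2, tall)

    def test_local_high_excluded(self):
        depths = np.array([11.5, 11.2, 10.0, 11.3, 11.6])
        assert not rr.evaluate_focal_point(depths, 2, BASE)

    def test_roll_boundary_exactly_five_metres_rolls(self):
        depths = np.array([10.0, 12.0, 15.0, 12.0, 10.0])
        assert not rr.evaluate_focal_point(depths, 2, BASE)  # range == 5.0

    def test_flat_boundary_half_metre_is_flat(self):
        depths = np.array([12.0, 12.5, 12.0, 12.5, 12.0])
        assert rr.evaluate_focal_point(depths, 2, BASE)  # range == 0.5

    def test_profile_end_cannot_satisfy_depression_rule(self):
        # end point sits 1 m below its single flank, but a depression needs
        # both sides; the 1-m window relief also exceeds the flat threshold
        depths = np.array([13.0, 12.0, 12.0, 12.0])
        assert not rr.evaluate_focal_point(depths, 0, BASE)

    def test_end_point_flat_rule_applies(self):
        depths = np.full(10, 9.0)
        assert rr.evaluate_focal_point(depths, 0, BASE)


class TestEvaluateTransect:
    def test_all_points_flagged_gives_100(self):
        res = rr.evaluate_transect(make_profile_obj(np.full(40, 12.0)))
        assert res.cover_pct_total == 100.0

    def test_cover_arithmetic(self):
        res = rr.evaluate_transect(make_profile_obj(np.full(40, 12.0)))
        n_flagged = res.accumulates.sum()
        assert res.cover_pct_total == pytest.approx(100.0 * n_flagged / 40)

    def test_shallow_deep_split_and_oracle(self):
        # 8-m shelf (15 pts) + 6-m dropoff + 16-m shelf (15 pts)
        spec = rr.TerrainSpec(
            segments=(rr.Segment("flat", 140.0), rr.Segment("dropoff", 50.0, 6.0),
                      rr.Segment("flat", 150.0)),
            base_depth_m=8.0,
        )
        depths = rr.make_profile(spec)["depth_m"].to_numpy()
        res = rr.evaluate_transect(make_profile_obj(depths))
        expected = naive_rubble_flags(depths)
        assert list(res.accumulates) == expected
        shallow = depths < 10.0
        assert res.cover_pct_shallow == pytest.approx(
            100.0 * sum(f for f, s in zip(expected, shallow) if s) / shallow.sum()
        )
        assert res.cover_pct_deep == pytest.approx(
            100.0 * sum(f for f, s in zip(expected, ~shallow) if s) / (~shallow).sum()
        )

    def test_filled_profile_invariant(self):
        depths = np.full(30, 14.0)
        res = rr.evaluate_transect(make_profile_obj(depths))
        filled_expected = np.where(res.accumulates, depths - 0.5, depths)
        np.testing.assert_array_equal(res.filled_depth_m, filled_expected)

    def test_flag_count_partition(self):
        rng = np.random.default_rng(2)
        depths = np.clip(10 + np.cumsum(rng.normal(0, 0.4, 60)), 3, None)
        res = rr.evaluate_transect(make_profile_obj(depths))
        n_sh = res.accumulates[res.section == "shallow"].sum()
        n_dp = res.accumulates[res.section == "deep"].sum()
        assert n_sh + n_dp == res.accumulates.sum()

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            rr.evaluate_profile_flags(np.array([]))

    def test_missing_depths_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rr.evaluate_profile_flags(np.array([5.0, np.nan, 6.0]))


class TestOracleEquivalence:
    def test_vectorised_equals_naive_on_random_profiles(self, random_profiles):
        for depths in random_profiles:
            fast = rr.evaluate_profile_flags(depths, BASE)
            assert list(fast) == naive_rubble_flags(depths)

    def test_scalar_path_equals_naive(self, random_profiles):
        for depths in random_profiles[:20]:
            scalar = [rr.evaluate_focal_point(depths, i, BASE)
                      for i in range(len(depths))]
            assert scalar == naive_rubble_flags(depths)

    def test_equivalence_under_perturbed_params(self, random_profiles):
        for name in rr.core.PARAM_NAMES:
            for factor in (0.8, 1.2):
                params = BASE.scaled(name, factor)
                for depths in random_profiles[:30]:
                    fast = rr.evaluate_profile_flags(depths, params)
                    assert list(fast) == naive_rubble_flags(
                        depths,
                        moving_window_m=params.moving_window_m,
                        rubble_height_m=params.rubble_height_m,
                        roll_depth_range_m=params.roll_depth_range_m,
                        flat_depth_change_m=params.flat_depth_change_m,
                    )


class TestInvariances:
    def test_translation_leaves_flags_unchanged(self, random_profiles):
        for depths in random_profiles[:50]:
            base_flags = rr.evaluate_profile_flags(depths, BASE)
            shifted = rr.evaluate_profile_flags(depths + 7.5, BASE)
            np.testing.assert_array_equal(base_flags, shifted)

    def test_reflection_reverses_flags(self, random_profiles):
        for depths in random_profiles[:50]:
            fwd = rr.evaluate_profile_flags(depths, BASE)
            rev = rr.evaluate_profile_flags(depths[::-1].copy(), BASE)
            np.testing.assert_array_equal(fwd, rev[::-1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_flat_threshold(self, seed):
        from reefrubble.synthetic import random_terrain_spec

        depths = rr.make_profile(
            random_terrain_spec(np.random.default_rng(seed))
        )["depth_m"].to_numpy()
        covers = [
            rr.evaluate_transect(
                make_profile_obj(depths),
                rr.RubbleParams(flat_depth_change_m=f),
            ).cover_pct_total
            for f in (0.25, 0.5, 1.0, 2.0)
        ]
        assert covers == sorted(covers)


class TestRubbleParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            rr.RubbleParams(rubble_height_m=0.0)
        with pytest.raises(ValueError):
            rr.RubbleParams(flat_depth_change_m=6.0)  # must stay below roll range

    def test_scaled_produces_new_params(self):
        p = BASE.scaled("moving_window_m", 1.2)
        assert p.moving_window_m == 60.0 and BASE.moving_window_m == 50.0
        assert p.half_window_samples() == 6
        assert BASE.scaled("moving_window_m", 0.8).half_window_samples() == 4
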