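"""Geometry of the building layout and the counterbalanced design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hexdir import city


class TestLayout:
    def test_building_counts_and_rings(self, layout):
        b = layout.buildings
        assert len(b) == 18
        assert (b.ring == "inner").sum() == 6
        assert (b.ring == "outer").sum() == 12

    def test_inner_ring_on_main_axes(self, layout):
        inner = layout.buildings[layout.buildings.ring == "inner"]
        radii = np.hypot(inner.x, inner.y)
        assert np.allclose(radii, 1.0)
        angles = np.degrees(np.arctan2(inner.y, inner.x)) % 360
        assert sorted(np.round(angles).astype(int) % 360) == [0, 60, 120, 180, 240, 300]

    def test_outer_ring_radii(self, layout):
        outer = layout.buildings[layout.buildings.ring == "outer"]
        radii = np.sort(np.hypot(outer.x, outer.y))
        assert np.allclose(radii[:6], np.sqrt(3.0))
        assert np.allclose(radii[6:], 2.0)

    def test_invalid_scale(self):
        with pytest.raises(city.DesignError):
            city.build_city_layout(scale=0)


class TestCombinations:
    def test_ten_directions_per_start_sixty_total(self, combos):
        assert len(combos) == 60
        assert (combos.groupby("start_id").size() == 10).all()

    def test_direction_availability_structure(self, combos):
        # brute-force oracle: every main-axis direction reachable from all 6
        # starts, every 30-degree-offset direction from exactly 4
        main = combos[combos.main_axis].groupby("direction_deg").size()
        offs = combos[~combos.main_axis].groupby("direction_deg").size()
        assert (main == 6).all() and len(main) == 6
        assert (offs == 4).all() and len(offs) == 6

    def test_all_angles_exact_multiples_of_30(self, combos, layout):
        coords = layout.coords()
        for r in combos.itertuples(index=False):
            v = coords[r.target_id] - coords[r.start_id]
            ang = np.degrees(np.arctan2(v[1], v[0])) % 360
            assert abs(ang - r.direction_deg) % 360 < 1e-9

    def test_starts_are_inner(self, combos, layout):
        inner = set(layout.inner_ids)
        assert set(combos.start_id) <= inner

    def test_inner_targets_only_on_offset_directions(self, combos):
        inner_tgt = combos[combos.target_ring == "inner"]
        assert len(inner_tgt) == 12
        assert (inner_tgt.direction_deg % 60 == 30).all()

    def test_rejects_broken_layout(self, layout):
        broken = city.CityLayout(buildings=layout.buildings.iloc[:10])
        with pytest.raises(city.DesignError):
            city.enumerate_combinations(broken)


class TestExclusions:
    @pytest.mark.parametrize("seed", [0, 1, 7, 99])
    def test_structure_after_exclusion(self, combos, seed):
        c48 = city.apply_exclusions(combos, seed)
        assert len(c48) == 48
        assert (c48.groupby("direction_deg").size() == 4).all()
        removed = combos.merge(
            c48, how="left", indicator=True,
            on=list(combos.columns)).query("_merge == 'left_only'")
        assert (removed.groupby("start_id").size() == 2).all()
        assert removed.main_axis.all()

    def test_inner_targets_never_excluded(self, combos):
        for seed in range(5):
            c48 = city.apply_exclusions(combos, seed)
            assert (c48.target_ring == "inner").sum() == 12


class TestDesign:
    def test_block_counterbalancing(self, trials):
        assert len(trials) == 96
        for _, block in trials.groupby("block"):
            assert len(block) == 24
            assert (block.direction_deg.value_counts() == 2).all()
            assert (block.start_id.value_counts() == 4).all()

    def test_each_combination_twice(self, trials):
        assert (trials.groupby(["start_id", "target_id"]).size() == 2).all()

    def test_per_direction_total_is_eight(self, trials):
        assert (trials.direction_deg.value_counts() == 8).all()

    def test_catch_trials(self, trials):
        per_block = trials.groupby("block").is_catch.sum()
        assert (per_block == 3).all()
        assert not trials[trials.within_block_index == 0].is_catch.any()
        assert trials.catch_view_correct.sum() == 6  # 50% of 12

    def test_onsets_increase_with_valid_gaps(self, trials):
        for _, block in trials.groupby("block"):
            onsets = block.sort_values("within_block_index").cue_onset_s.to_numpy()
            assert (np.diff(onsets) >= 12.0).all()
            ends = block.imagination_end_s - block.cue_onset_s
            assert np.allclose(ends, 12.0)

    def test_order_randomised_across_seeds(self, combos48):
        t1 = city.generate_design(combos48, seed=1)
        t2 = city.generate_design(combos48, seed=2)
        assert not t1.direction_deg.equals(t2.direction_deg)

    def test_validate_flags_broken_table(self, trials):
        bad = trials.copy()
        bad.loc[0, "direction_deg"] = 15
        assert city.validate_design(bad)
        assert city.validate_design(trials) == []


class TestPairLabels:
    def test_partition_counts(self, labels):
        assert len(labels) == 4560
        assert (labels.rem60 == 0).sum() == 2256
        assert (labels.rem60 == 30).sum() == 2304
        # one-fold conditions also partition: no delta strictly in (30, 60)
        assert ((labels.delta_deg <= 30) | (labels.delta_deg >= 60)).all()

    def test_inner_ring_pairs(self, labels):
        inner = labels.both_inner_target
        assert inner.sum() == 276
        assert (labels.loc[inner, "rem60"] == 0).all()

    def test_counts_invariant_to_exclusion_seed(self, combos, layout):
        for seed in [3, 11, 42]:
            c48 = city.apply_exclusions(combos, seed)
            t = city.generate_design(c48, seed=seed)
            lb = city.label_pairs(t, layout)
            assert (lb.rem60 == 0).sum() == 2256
            assert (lb.rem60 == 30).sum() == 2304
            assert lb.both_inner_target.sum() == 276

    def test_same_combo_implies_identical_vectors(self, labels):
        sc = labels[labels.same_combo]
        assert (sc.delta_deg == 0).all()
        assert np.allclose(sc.dist_absdiff, 0.0)

    def test_same_block_pair_count(self, labels):
        assert labels.same_block.sum() == 4 * 24 * 23 // 2

    def test_rem90_consistent_with_delta(self, labels):
        assert (labels.rem90 == labels.delta_deg % 90).all()

    def test_distance_measures_positive_and_symmetric_roles(self, labels):
        assert (labels.dist_mean > 0).all()
        assert (labels.dist_absdiff >= 0).all()
        assert (labels.dist_neighborhood >= 0).all()


@settings(max_examples=200, deadline=None)
@given(a=st.floats(0, 360, allow_nan=False), b=st.floats(0, 360, allow_nan=False),
       k=st.integers(-3, 3))
def test_wrapped_delta_properties(a, b, k):
    d = city.wrapped_delta_deg(a, b)
    assert 0.0 <= d <= 180.0
    assert np.isclose(d, city.wrapped_delta_deg(b, a))
    assert np.isclose(d, city.wrapped_delta_deg(a + 360.0 * k, b), atol=1e-6)
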