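import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselkit import traits
from vesselkit.traits import (
    EmptyRingError,
    VesselRecord,
    WaterProperties,
    combine_cores,
    compute_ring_traits,
    compute_trait_table,
    diameter_from_area,
    filter_vessels,
    grouping_indices,
    hydraulically_weighted_diameter,
    theoretical_conductivity,
    vulnerability_index,
)

from _oracles import brute_force_ring_traits, random_ring
from conftest import make_ring, vessels_frame


def _vessels(areas, groups=None):
    return make_ring(areas, groups).vessels


class TestFilter:
    def test_boundary_value_retained(self):
        kept = filter_vessels(_vessels([4000, 5000, 6000]), 5000)
        assert [v.lumen_area for v in kept] == [5000, 6000]

    def test_zero_threshold_is_identity(self):
        vs = _vessels([6000, 7000])
        assert filter_vessels(vs, 0) == vs

    def test_depleted_pair_becomes_solitary(self):
        vs = _vessels([4000, 9000], groups=["p", "p"])
        kept = filter_vessels(vs, 5000)
        assert len(kept) == 1
        gi, svi = grouping_indices(kept)
        assert gi == 1.0 and svi == 1.0

    def test_order_preserved_and_empty_allowed(self):
        vs = _vessels([9000, 4000, 8000, 7000])
        assert [v.lumen_area for v in filter_vessels(vs, 7500)] == [9000, 8000]
        assert filter_vessels(vs, 1e7) == []


class TestDiameter:
    @pytest.mark.parametrize(
        "area,expected",
        [(7853.98, 100.0), (5000.0, 2 * math.sqrt(5000 / math.pi))],
    )
    def test_round_vessel(self, area, expected):
        assert diameter_from_area(area) == pytest.approx(expected, rel=1e-5)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            diameter_from_area(0.0)


class TestHWD:
    def test_identical_diameters(self):
        assert hydraulically_weighted_diameter([100, 100, 100]) == pytest.approx(100)

    def test_two_diameters(self):
        expected = (100**5 + 200**5) / (100**4 + 200**4)
        assert hydraulically_weighted_diameter([100, 200]) == pytest.approx(expected)
        assert expected == pytest.approx(194.1176, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hydraulically_weighted_diameter([])


class TestTHC:
    def test_single_vessel_si_conversion(self):
        # pi * 998.2 * (1e-4 m)^4 / (128 * 1.002e-9 MPa s * 1e-6 m^2)
        thc = theoretical_conductivity([100.0], 1.0)
        assert thc == pytest.approx(2.445, rel=1e-3)

    def test_empty_is_zero(self):
        assert theoretical_conductivity([], 3.7) == 0.0

    def test_aoi_scaling(self):
        d = [80.0, 120.0, 95.0]
        assert theoretical_conductivity(d, 2.0) == pytest.approx(
            theoretical_conductivity(d, 1.0) / 2.0
        )

    def test_additive_over_vessels(self):
        a = theoretical_conductivity([100.0], 1.0)
        b = theoretical_conductivity([150.0], 1.0)
        assert theoretical_conductivity([100.0, 150.0], 1.0) == pytest.approx(a + b)

    def test_invalid_aoi(self):
        with pytest.raises(ValueError):
            theoretical_conductivity([100.0], 0.0)


class TestVI:
    @pytest.mark.parametrize(
        "d,vfreq,expected", [(100, 10, 10.0), (178.1, 11.3, 15.7611)]
    )
    def test_values(self, d, vfreq, expected):
        assert vulnerability_index(d, vfreq) == pytest.approx(expected, abs=1e-3)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            vulnerability_index(150, 0)


class TestGrouping:
    def test_mixed_population(self):
        # 6 solitary + 2 pairs: 10 vessels in 8 groups
        areas = [6000] * 10
        groups = ["s1", "s2", "s3", "s4", "s5", "s6", "p1", "p1", "p2", "p2"]
        gi, svi = grouping_indices(_vessels(areas, groups))
        assert gi == pytest.approx(1.25)
        assert svi == pytest.approx(0.6)

    def test_all_solitary(self):
        gi, svi = grouping_indices(_vessels([6000] * 5))
        assert (gi, svi) == (1.0, 1.0)

    def test_single_large_group(self):
        gi, svi = grouping_indices(_vessels([6000] * 4, ["g"] * 4))
        assert (gi, svi) == (4.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grouping_indices([])


class TestRingTraits:
    def test_hand_worked_example(self):
        ring = make_ring([7853.98, 7853.98], aoi=1.0)
        rec = compute_ring_traits(ring)
        assert rec.la_mean == pytest.approx(7853.98)
        assert rec.vfreq == pytest.approx(2.0)
        assert rec.vfrac == pytest.approx(0.0157, abs=2e-4)
        assert rec.hwd == pytest.approx(100.0, rel=1e-5)
        assert rec.vi == pytest.approx(50.0, rel=1e-5)
        assert rec.gi == 1.0 and rec.svi == 1.0
        assert rec.level == "core"

    def test_all_below_threshold_is_empty_ring(self):
        with pytest.raises(EmptyRingError):
            compute_ring_traits(make_ring([3000, 4000]))

    def test_vfrac_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            areas, groups, aoi = random_ring(rng)
            if (areas >= 5000).sum() == 0:
                continue
            rec = compute_ring_traits(make_ring(areas, groups, aoi=aoi))
            assert rec.vfrac == pytest.approx(rec.vfreq * rec.la_mean * 1e-6, rel=1e-9)

    def test_brute_force_oracle_small_rings(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            areas, groups, aoi = random_ring(rng)
            expected = brute_force_ring_traits(areas, groups, aoi)
            if expected is None:
                continue
            rec = compute_ring_traits(make_ring(areas, groups, aoi=aoi))
            for name in traits.TRAIT_NAMES:
                assert rec.trait(name) == pytest.approx(expected[name], rel=1e-9)
            checked += 1


class TestPowerMeanProperty:
    @given(
        st.lists(st.floats(min_value=5000, max_value=1e6), min_size=1, max_size=30)
    )
    @settings(deadline=None, max_examples=60)
    def test_hwd_at_least_mean_diameter(self, areas):
        d = [2 * math.sqrt(a / math.pi) for a in areas]
        hwd = hydraulically_weighted_diameter(d)
        assert hwd >= np.mean(d) - 1e-9 * np.mean(d)

    def test_equality_iff_all_equal(self):
        assert hydraulically_weighted_diameter([70.0] * 5) == pytest.approx(70.0)
        assert hydraulically_weighted_diameter([70.0, 90.0]) > 80.0


class TestFilterMonotonicity:
    @given(
        st.lists(st.floats(min_value=1000, max_value=60000), min_size=2, max_size=25),
        st.floats(min_value=0, max_value=20000),
        st.floats(min_value=0, max_value=20000),
    )
    @settings(deadline=None, max_examples=60)
    def test_raising_threshold(self, areas, t1, t2):
        lo, hi = sorted((t1, t2))
        ring_lo = make_ring(areas)
        try:
            rec_lo = compute_ring_traits(ring_lo, min_area=lo)
            rec_hi = compute_ring_traits(ring_lo, min_area=hi)
        except EmptyRingError:
            return
        assert rec_hi.n_vessels <= rec_lo.n_vessels
        assert rec_hi.vfreq <= rec_lo.vfreq
        assert rec_hi.vfrac <= rec_lo.vfrac + 1e-12
        assert rec_hi.la_mean >= rec_lo.la_mean - 1e-9


class TestCombineCores:
    def _ring(self, core, areas, aoi=1.0):
        return make_ring(areas, aoi=aoi, core=core)

    def test_identical_cores_pooling(self):
        a = self._ring("A", [8000.0, 9000.0])
        b = self._ring("B", [8000.0, 9000.0])
        pooled = combine_cores([a, b])
        single = compute_ring_traits(a)
        assert pooled.la_mean == pytest.approx(single.la_mean)
        assert pooled.vfreq == pytest.approx(single.vfreq)  # same density
        assert pooled.level == "combined" and pooled.core_id is None

    def test_single_core_passthrough(self):
        a = self._ring("A", [8000.0, 12000.0])
        combined = combine_cores([a])
        core = compute_ring_traits(a)
        for name in traits.TRAIT_NAMES:
            assert combined.trait(name) == pytest.approx(core.trait(name))

    def test_pooled_two_core_example(self):
        area_100 = math.pi * 50.0**2
        area_200 = math.pi * 100.0**2
        a = self._ring("A", [area_100])
        b = self._ring("B", [area_200])
        pooled = combine_cores([a, b])
        assert pooled.vfreq == pytest.approx(1.0)
        assert pooled.hwd == pytest.approx(194.1176, abs=1e-3)

    def test_mismatched_identifiers_rejected(self):
        a = make_ring([8000.0], tree="t1")
        b = make_ring([8000.0], tree="t2", core="B")
        with pytest.raises(ValueError):
            combine_cores([a, b])

    def test_group_ids_do_not_merge_across_cores(self):
        a = make_ring([8000.0, 9000.0], groups=["g1", "g1"], core="A")
        b = make_ring([8500.0, 9500.0], groups=["g1", "g1"], core="B")
        pooled = combine_cores([a, b])
        assert pooled.gi == pytest.approx(2.0)  # two pairs, not one quad
        assert pooled.svi == 0.0


class TestTraitTable:
    def _frame(self):
        rows = []
        rng = np.random.default_rng(3)
        for tree in ("t1", "t2"):
            for core in ("A", "B"):
                for year in (2017, 2018):
                    for i in range(6):
                        rows.append(
                            (tree, "park", core, year, 2.0,
                             float(rng.uniform(3000, 40000)), f"g{i // 2}")
                        )
        return vessels_frame(rows)

    def test_matches_object_path(self):
        frame = self._frame()
        table = compute_trait_table(frame)
        rings = traits.rings_from_frame(frame)
        for ring in rings:
            rec = compute_ring_traits(ring)
            row = table[
                (table.tree_id == ring.tree_id)
                & (table.core_id == ring.core_id)
                & (table.ring_year == ring.ring_year)
                & (table.level == "core")
            ].iloc[0]
            for name in traits.TRAIT_NAMES:
                assert row[name] == pytest.approx(rec.trait(name), rel=1e-12)

    def test_combined_matches_combine_cores(self):
        frame = self._frame()
        table = compute_trait_table(frame)
        rings = traits.rings_from_frame(frame)
        by_ty = {}
        for r in rings:
            by_ty.setdefault((r.tree_id, r.ring_year), []).append(r)
        for (tree, year), group in by_ty.items():
            rec = combine_cores(group)
            row = table[
                (table.tree_id == tree)
                & (table.ring_year == year)
                & (table.level == "combined")
            ].iloc[0]
            for name in traits.TRAIT_NAMES:
                assert row[name] == pytest.approx(rec.trait(name), rel=1e-12)

    def test_mean_combine_option(self):
        frame = self._frame()
        table = compute_trait_table(frame, combine="mean")
        core = table[table.level == "core"]
        comb = table[table.level == "combined"].set_index(["tree_id", "ring_year"])
        for (tree, year), sub in core.groupby(["tree_id", "ring_year"]):
            assert comb.loc[(tree, year), "LA"] == pytest.approx(sub["LA"].mean())

    def test_inconsistent_aoi_rejected(self):
        frame = self._frame()
        frame.loc[0, "aoi_mm2"] = 99.0
        with pytest.raises(ValueError, match="aoi"):
            compute_trait_table(frame)


def test_water_properties_validation():
    with pytest.raises(ValueError):
        WaterProperties(eta=0.0)
    with pytest.raises(ValueError):
        VesselRecord("t", "park", "A", 2018, -5.0, "g")
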