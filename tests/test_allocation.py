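import numpy as np
import pandas as pd
import pytest

from hanppcube.allocation import (
    ReconciliationLog,
    allocate_builtup,
    allocate_sequential,
    classify_wilderness,
    gap_fill_radius,
    split_cropland,
)
from hanppcube.grid import CountryPartition


def proximity_oracle(stack, remainder, seed_mask):
    """Independent shell-filling reference: explicit loops over cells
    grouped by exact Euclidean distance to the nearest seed cell."""
    alloc = np.zeros_like(stack)
    seeds = list(zip(*np.nonzero(seed_mask)))
    cells = list(zip(*np.nonzero(stack > 0)))
    dist = {}
    for (r, c) in cells:
        if seeds:
            dist[(r, c)] = min(np.hypot(r - sr, c - sc) for sr, sc in seeds)
        else:
            dist[(r, c)] = 0.0
    left = remainder
    for d in sorted(set(np.round(v, 9) for v in dist.values())):
        shell = [rc for rc in cells if round(dist[rc], 9) == d]
        cap = sum(stack[rc] for rc in shell)
        if left >= cap:
            for rc in shell:
                alloc[rc] = stack[rc]
            left -= cap
        else:
            for rc in shell:
                alloc[rc] = stack[rc] * left / cap
            left = 0
            break
    return alloc


class TestAllocateSequential:
    def test_zero_target_allocates_nothing(self):
        stacks = [np.ones((3, 3))]
        allocs, short = allocate_sequential(0.0, stacks)
        assert np.all(allocs[0] == 0) and short == 0

    def test_proportional_within_class1(self):
        s1 = np.array([[10.0, 10.0, 0.0]])
        allocs, short = allocate_sequential(10.0, [s1])
        assert np.allclose(allocs[0], [[5.0, 5.0, 0.0]])
        assert short == 0

    def test_spillover_follows_distance_to_class1(self, rng):
        # class1 in one corner, class2 elsewhere; target exceeds class1
        shape = (8, 8)
        s1 = np.zeros(shape)
        s1[0, 0] = s1[0, 1] = 4.0
        s2 = np.where(s1 > 0, 0.0, rng.uniform(0.5, 2.0, shape))
        target = 8.0 + 11.0
        allocs, short = allocate_sequential(target, [s1, s2])
        assert np.allclose(allocs[0], s1)
        oracle = proximity_oracle(s2, 11.0, s1 > 0)
        assert np.allclose(allocs[1], oracle)
        assert short == 0

    def test_third_class_and_shortfall(self):
        s1 = np.array([[1.0, 0.0]])
        s2 = np.array([[0.0, 2.0]])
        s3 = np.array([[0.5, 0.0]])
        allocs, short = allocate_sequential(5.0, [s1, s2, s3])
        assert sum(a.sum() for a in allocs) == pytest.approx(3.5)
        assert short == pytest.approx(1.5)

    def test_monotone_in_target(self, rng):
        shape = (6, 6)
        stacks = [rng.uniform(0, 2, shape) for _ in range(3)]
        lo, _ = allocate_sequential(5.0, stacks)
        hi, _ = allocate_sequential(9.0, stacks)
        total_lo = sum(lo)
        total_hi = sum(hi)
        assert np.all(total_hi >= total_lo - 1e-12)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            allocate_sequential(-1.0, [np.ones((2, 2))])


class TestBuiltupTransfer:
    def test_stated_rule(self):
        urban = np.array([[0.2]])
        crop = np.array([[1.0]])
        bu, cl = allocate_builtup(urban, crop)
        assert bu[0, 0] == pytest.approx(0.25)
        assert cl[0, 0] == pytest.approx(0.95)

    def test_no_urban_no_cropland(self):
        bu, cl = allocate_builtup(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.all(bu == 0) and np.all(cl == 0)

    def test_national_transfer_is_five_percent(self, rng):
        crop = rng.uniform(0, 3, (5, 5))
        bu, cl = allocate_builtup(np.zeros((5, 5)), crop)
        assert bu.sum() == pytest.approx(0.05 * crop.sum())
        assert (bu + cl).sum() == pytest.approx(crop.sum())


class TestSplitCropland:
    def make_inputs(self):
        # one country, two cells, two crops with known pattern shares
        cropland = np.array([[100.0, 100.0]])
        part = CountryPartition(country_id=np.array([[1, 1]]))
        fao_land = pd.DataFrame([{"country": 1, "cropland_km2": 200.0}])
        fao_crops = pd.DataFrame([
            {"country": 1, "crop": "A", "area_harvested_km2": 100.0},
            {"country": 1, "crop": "B", "area_harvested_km2": 60.0},
        ])
        spam_phys = {"A": np.array([[0.75, 0.5]]), "B": np.array([[0.25, 0.5]])}
        spam_mc = {"A": np.ones((1, 2)), "B": np.ones((1, 2))}
        return cropland, part, fao_land, fao_crops, spam_phys, spam_mc

    def test_two_crop_two_cell_algebraic_oracle(self):
        cropland, part, land, crops, phys, mc = self.make_inputs()
        log = ReconciliationLog()
        split = split_cropland(cropland, part, land, crops, phys, mc, log)
        # CLharv per cell = cropland × (Σ harvested / cropland_FAO) = 100×0.8 = 80
        # base_A = 80·[0.75, 0.5] = [60, 40] → f_A = 100/100 = 1.0
        # base_B = 80·[0.25, 0.5] = [20, 40] → f_B = 60/60 = 1.0
        assert np.allclose(split.harvested["A"], [[60.0, 40.0]])
        assert np.allclose(split.harvested["B"], [[20.0, 40.0]])
        assert split.harvested["A"].sum() == pytest.approx(100.0)
        assert split.harvested["B"].sum() == pytest.approx(60.0)
        assert split.f_fao[(1, "A")] == pytest.approx(1.0)

    def test_fallow_minimum_from_census(self):
        cropland, part, land, crops, phys, mc = self.make_inputs()
        log = ReconciliationLog()
        split = split_cropland(cropland, part, land, crops, phys, mc, log)
        # FALLOWmin = 200 − 160 = 40 nationally
        assert split.fallow_min_fao[1] == pytest.approx(40.0)

    def test_fallow_split_half_fodder_half_fallow(self):
        cropland, part, land, crops, phys, mc = self.make_inputs()
        log = ReconciliationLog()
        split = split_cropland(cropland, part, land, crops, phys, mc, log)
        resid = cropland - sum(split.physical.values())
        assert np.allclose(split.fodder, 0.5 * resid)
        assert np.allclose(split.fallow, 0.5 * resid)
        # per-cell identity closes exactly
        total = sum(split.physical.values()) + split.fodder + split.fallow
        assert np.allclose(total, cropland, rtol=1e-12)

    def test_multicropping_shrinks_physical_area(self):
        cropland, part, land, crops, phys, mc = self.make_inputs()
        mc = {"A": np.full((1, 2), 2.0), "B": np.ones((1, 2))}
        log = ReconciliationLog()
        split = split_cropland(cropland, part, land, crops, phys, mc, log)
        assert np.allclose(split.physical["A"], split.harvested["A"] / 2.0)
        assert np.allclose(split.physical["B"], split.harvested["B"])

    def test_census_only_crop_spread_proportionally(self):
        cropland, part, land, crops, phys, mc = self.make_inputs()
        crops = pd.concat([crops, pd.DataFrame([
            {"country": 1, "crop": "C", "area_harvested_km2": 10.0}])], ignore_index=True)
        phys["C"] = np.zeros((1, 2))
        mc["C"] = np.ones((1, 2))
        log = ReconciliationLog()
        split = split_cropland(cropland, part, land, crops, phys, mc, log)
        assert np.allclose(split.harvested["C"], [[5.0, 5.0]])
        assert log.events("census_only_crop")

    def test_zero_cropland_with_harvest_logs_error(self):
        cropland = np.zeros((1, 2))
        part = CountryPartition(country_id=np.array([[1, 1]]))
        land = pd.DataFrame([{"country": 1, "cropland_km2": 0.0}])
        crops = pd.DataFrame([{"country": 1, "crop": "A", "area_harvested_km2": 5.0}])
        phys = {"A": np.ones((1, 2))}
        mc = {"A": np.ones((1, 2))}
        log = ReconciliationLog()
        split_cropland(cropland, part, land, crops, phys, mc, log)
        assert log.events("reconciliation_error")


def test_gap_fill_uses_nearby_nonzero_donors():
    vals = np.zeros((5, 5))
    vals[0, 0] = 4.0
    vals[0, 2] = 2.0
    valid = vals > 0
    targets = np.zeros((5, 5), dtype=bool)
    targets[0, 1] = True   # between both donors
    targets[4, 4] = True   # far away, radius excludes donors
    out = gap_fill_radius(vals, valid, targets, radius=2)
    assert out[0, 1] == pytest.approx(3.0)
    assert out[4, 4] == 0.0


class TestWilderness:
    def test_low_productivity_dominates_footprint(self):
        npp = np.full((1, 3), 10.0)
        fp = np.array([[0.0, 25.0, 50.0]])
        nps, core, peri = classify_wilderness(npp, fp, np.zeros((1, 3)), np.zeros((1, 3)))
        assert nps.all() and not core.any() and not peri.any()

    def test_forest_zone_needs_both_criteria_for_core(self):
        npp = np.full((1, 2), 100.0)
        fz = np.ones((1, 2))
        fp = np.zeros((1, 2))
        ifl = np.array([[1.0, 0.0]])
        nps, core, peri = classify_wilderness(npp, fp, ifl, fz)
        assert core[0, 0] and not core[0, 1]
        assert peri[0, 1] and not peri[0, 0]

    def test_outside_forest_zone_footprint_alone_makes_core(self):
        npp = np.full((1, 2), 100.0)
        fz = np.zeros((1, 2))
        fp = np.array([[0.0, 3.0]])
        nps, core, peri = classify_wilderness(npp, fp, np.zeros((1, 2)), fz)
        assert core[0, 0] and not core[0, 1]
        assert not peri.any()

    def test_footprint_range_validated(self):
        with pytest.raises(ValueError):
            classify_wilderness(np.ones((1, 1)), np.array([[60.0]]),
                                np.zeros((1, 1)), np.zeros((1, 1)))
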