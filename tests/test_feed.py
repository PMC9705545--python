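"""Feed demand arithmetic, land allocation and the feed balance."""

import numpy as np
import pytest

from foragecast.feed import (
    Allocation,
    BreedProfile,
    EXOTIC,
    HerdScenario,
    LOCAL,
    LAND_2050,
    LAND_CURRENT,
    LandScenario,
    MGMT_HIGH_YIELD,
    MGMT_LOW_YIELD,
    ManagementScenario,
    RegionHerd,
    SCENARIO_A,
    SCENARIO_B,
    allocate_best,
    annual_dm_per_head,
    demand_increase_ratio,
    feed_balance,
    herd_demand,
    pasture_area_ha,
    species_contribution,
)
from foragecast.raster import GridSpec, RegionMask, SuitabilitySurface, cell_area_grid
from foragecast.feed import KM2_TO_HA

# census head counts and the resulting whole-ton demands under the two
# herd-composition scenarios (93:7 and 60:40 local:exotic)
REGION_DEMANDS = [
    ("Amhara", 14_710_911, 30_606_050, 48_325_343),
    ("Oromia", 22_925_730, 47_696_981, 75_311_023),
    ("Tigray", 4_578_181, 9_524_906, 15_039_325),
    ("SNNP", 11_215_636, 23_334_131, 36_843_364),
]


class TestDemand:
    def test_per_head_requirements(self):
        assert annual_dm_per_head(LOCAL) == pytest.approx(1.825)
        assert annual_dm_per_head(EXOTIC) == pytest.approx(5.475)
        assert annual_dm_per_head(EXOTIC) / annual_dm_per_head(LOCAL) == pytest.approx(
            3.0
        )

    @pytest.mark.parametrize("region, n, demand_a, demand_b", REGION_DEMANDS)
    def test_region_demand_whole_tons(self, region, n, demand_a, demand_b):
        herd = RegionHerd(region, n)
        assert herd_demand(herd, SCENARIO_A) == demand_a
        assert herd_demand(herd, SCENARIO_B) == demand_b

    def test_totals_sum_of_rounded_regions(self):
        total_a = sum(herd_demand(RegionHerd(r, n), SCENARIO_A) for r, n, *_ in REGION_DEMANDS)
        total_b = sum(herd_demand(RegionHerd(r, n), SCENARIO_B) for r, n, *_ in REGION_DEMANDS)
        assert total_a == 111_162_068
        assert total_b == 175_519_055

    def test_zero_head_zero_demand(self):
        assert herd_demand(RegionHerd("empty", 0), SCENARIO_A) == 0

    def test_linear_in_head_count(self):
        h1 = herd_demand(RegionHerd("x", 1_000_000), SCENARIO_A)
        h2 = herd_demand(RegionHerd("x", 2_000_000), SCENARIO_A)
        assert h2 == 2 * h1

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (SCENARIO_A, SCENARIO_A, 100),
            (SCENARIO_A, SCENARIO_B, 158),
            (HerdScenario("all-local", 1.0, 0.0), HerdScenario("all-exotic", 0.0, 1.0), 300),
        ],
    )
    def test_demand_increase_ratio(self, a, b, expected):
        assert demand_increase_ratio(a, b) == expected

    def test_scenario_fractions_validated(self):
        with pytest.raises(ValueError):
            HerdScenario("bad", 0.5, 0.4)
        with pytest.raises(ValueError):
            BreedProfile("bad", -1.0)


class TestPastureArithmetic:
    @pytest.mark.parametrize(
        "area, land, frac, expected",
        [
            (1_000_000.0, LAND_CURRENT, 50.0, 75_000.0),
            (1_000_000.0, LAND_CURRENT, 0.0, 0.0),
        ],
    )
    def test_pasture_area(self, area, land, frac, expected):
        assert pasture_area_ha(area, land, frac) == expected

    def test_land_scenarios_in_ratio_two_thirds(self):
        a10 = pasture_area_ha(5e6, LAND_2050, 33.0)
        a15 = pasture_area_ha(5e6, LAND_CURRENT, 33.0)
        assert a10 / a15 == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize(
        "area, yld, demand, expected",
        [(10_000.0, 5.7, 57_000.0, 100.0), (0.0, 30.0, 1000.0, 0.0),
         (1000.0, 5.7, 57_000.0, 10.0)],
    )
    def test_species_contribution(self, area, yld, demand, expected):
        assert species_contribution(area, yld, demand) == pytest.approx(expected)

    def test_zero_demand_rejected(self):
        with pytest.raises(ValueError):
            species_contribution(1.0, 1.0, 0.0)

    def test_low_yield_never_beats_high_yield(self):
        for s in ("Buffel", "Napier", "Rhodes"):
            low = species_contribution(1000.0, MGMT_LOW_YIELD.yields_t_per_ha[s], 1e6)
            high = species_contribution(1000.0, MGMT_HIGH_YIELD.yields_t_per_ha[s], 1e6)
            assert low <= high


def surfaces_on(spec, **scores):
    return {
        name: SuitabilitySurface(spec, np.asarray(arr, dtype=float), species_name=name)
        for name, arr in scores.items()
    }


def one_region_mask(spec):
    return RegionMask(
        spec=spec, ids=np.ones((spec.n_rows, spec.n_cols), dtype=np.int32),
        names={1: "toy"},
    )


class TestAllocation:
    spec = GridSpec(n_rows=2, n_cols=2, cell_size=0.5, west=0.0, north=10.0)

    def test_sole_suitable_species_takes_all(self):
        surfaces = surfaces_on(
            self.spec,
            Buffel=np.full((2, 2), 80.0),
            Napier=np.zeros((2, 2)),
            Rhodes=np.zeros((2, 2)),
        )
        mask = one_region_mask(self.spec)
        alloc = allocate_best(surfaces, mask, 1, LAND_CURRENT, MGMT_HIGH_YIELD)
        total = cell_area_grid(self.spec).sum() * KM2_TO_HA * 0.15
        assert alloc.areas_ha["Buffel"] == pytest.approx(total)
        assert alloc.areas_ha["Napier"] == 0.0
        assert alloc.other_grass_ha == 0.0

    def test_score_times_yield_decides(self):
        # Napier 50 x 30 = 1500 < Rhodes 90 x 18 = 1620 -> Rhodes wins
        surfaces = surfaces_on(
            self.spec,
            Buffel=np.zeros((2, 2)),
            Napier=np.full((2, 2), 50.0),
            Rhodes=np.full((2, 2), 90.0),
        )
        mask = one_region_mask(self.spec)
        alloc = allocate_best(surfaces, mask, 1, LAND_CURRENT, MGMT_HIGH_YIELD)
        assert alloc.areas_ha["Rhodes"] > 0.0
        assert alloc.areas_ha["Napier"] == 0.0

    def test_threshold_gates_candidates(self):
        # Napier below threshold loses to a suitable Buffel despite utility
        surfaces = surfaces_on(
            self.spec,
            Buffel=np.full((2, 2), 45.0),  # 45 x 16 = 720
            Napier=np.full((2, 2), 39.0),  # 39 x 30 = 1170 but < 40
            Rhodes=np.zeros((2, 2)),
        )
        mask = one_region_mask(self.spec)
        alloc = allocate_best(surfaces, mask, 1, LAND_CURRENT, MGMT_HIGH_YIELD)
        assert alloc.areas_ha["Buffel"] > 0.0
        assert alloc.areas_ha["Napier"] == 0.0

    def test_unsuitable_cells_go_to_other_grasses(self):
        scores = np.array([[80.0, 10.0], [10.0, 10.0]])
        surfaces = surfaces_on(
            self.spec, Buffel=scores, Napier=np.zeros((2, 2)), Rhodes=np.zeros((2, 2))
        )
        mask = one_region_mask(self.spec)
        alloc = allocate_best(surfaces, mask, 1, LAND_CURRENT, MGMT_HIGH_YIELD)
        assert alloc.other_grass_ha > 0.0
        assert alloc.total_ha == pytest.approx(
            cell_area_grid(self.spec).sum() * KM2_TO_HA * 0.15
        )

    def test_matches_brute_force_argmax(self, rng):
        spec = GridSpec(n_rows=8, n_cols=8, cell_size=0.5, west=0.0, north=20.0)
        scores = {s: rng.uniform(0, 100, (8, 8)) for s in ("Buffel", "Napier", "Rhodes")}
        surfaces = surfaces_on(spec, **scores)
        mask = one_region_mask(spec)
        mgmt = MGMT_HIGH_YIELD
        alloc = allocate_best(surfaces, mask, 1, LAND_CURRENT, mgmt)
        w = cell_area_grid(spec) * KM2_TO_HA * 0.15
        want = {s: 0.0 for s in scores}
        other = 0.0
        for r in range(8):
            for c in range(8):
                cands = [
                    (scores[s][r, c] * mgmt.yields_t_per_ha[s], scores[s][r, c], -i, s)
                    for i, s in enumerate(("Buffel", "Napier", "Rhodes"))
                    if scores[s][r, c] >= 40.0
                ]
                if not cands:
                    other += w[r, c]
                else:
                    want[max(cands)[3]] += w[r, c]
        for s in want:
            assert alloc.areas_ha[s] == pytest.approx(want[s], rel=1e-12)
        assert alloc.other_grass_ha == pytest.approx(other, rel=1e-12)

    def test_mass_conservation(self, rng):
        spec = GridSpec(n_rows=6, n_cols=9, cell_size=0.5, west=0.0, north=30.0)
        surfaces = surfaces_on(
            spec, **{s: rng.uniform(0, 100, (6, 9)) for s in ("Buffel", "Napier", "Rhodes")}
        )
        mask = one_region_mask(spec)
        for land in (LAND_CURRENT, LAND_2050):
            alloc = allocate_best(surfaces, mask, 1, land, MGMT_HIGH_YIELD)
            expected = cell_area_grid(spec).sum() * KM2_TO_HA * land.pasture_fraction
            assert alloc.total_ha == pytest.approx(expected, rel=1e-12)


class TestFeedBalance:
    def test_supply_equal_demand_balances(self):
        alloc = Allocation("toy", {"Buffel": 1000.0}, other_grass_ha=0.0,
                           pasture_fraction=0.15)
        mgmt = ManagementScenario("t", {"Buffel": 10.0})
        rep = feed_balance(alloc, mgmt, demand_t=10_000.0)
        assert rep.total_contribution_pct == pytest.approx(100.0)
        assert rep.surplus_pct == pytest.approx(0.0)

    def test_doubling_yields_doubles_contributions(self):
        alloc = Allocation("toy", {"Buffel": 500.0, "Napier": 250.0},
                           other_grass_ha=100.0, pasture_fraction=0.15)
        m1 = ManagementScenario("a", {"Buffel": 8.0, "Napier": 20.0},
                                other_grass_yield=5.7)
        m2 = ManagementScenario("b", {"Buffel": 16.0, "Napier": 40.0},
                                other_grass_yield=11.4)
        r1 = feed_balance(alloc, m1, 1e5)
        r2 = feed_balance(alloc, m2, 1e5)
        for s in ("Buffel", "Napier"):
            assert r2.contribution_pct[s] == pytest.approx(2 * r1.contribution_pct[s])
        assert r2.total_contribution_pct == pytest.approx(2 * r1.total_contribution_pct)

    def test_hand_computed_two_species_ledger(self):
        # 300 ha x 16 t/ha = 4800 t; 100 ha x 18 t/ha = 1800 t;
        # 50 ha x 5.7 = 285 t; demand 13770 t
        alloc = Allocation("toy", {"Buffel": 300.0, "Rhodes": 100.0},
                           other_grass_ha=50.0, pasture_fraction=0.1)
        mgmt = ManagementScenario("t", {"Buffel": 16.0, "Rhodes": 18.0})
        rep = feed_balance(alloc, mgmt, demand_t=13_770.0)
        assert rep.supply_t == {"Buffel": 4800.0, "Rhodes": 1800.0}
        assert rep.contribution_pct["Buffel"] == pytest.approx(100 * 4800 / 13770)
        assert rep.other_grass_supply_t == pytest.approx(285.0)
        assert rep.total_contribution_pct == pytest.approx(
            100 * (4800 + 1800 + 285) / 13770
        )
        assert rep.uncertainty_band_pct == 28.0
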