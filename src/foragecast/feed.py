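"""Livestock dry-matter feed demand and forage supply scenarios.

Demand: cattle eat 2.5% of live body weight in dry matter (DM) per day;
local breeds weigh ~200 kg and exotic (improved dairy) breeds ~600 kg, so a
local head needs 1.825 t DM/yr and an exotic head 5.475 t DM/yr.  A herd
scenario is a local:exotic mix — scenario A keeps the current 93:7 split,
scenario B intensifies to 60:40.  Regional demand is head count times the
mix-weighted per-head requirement, rounded to whole tons half away from
zero at region level; totals are sums of the rounded regions.

Supply: a land scenario fixes the fraction of a region kept as pasture (15%
now, 10% projected for 2050); a management scenario fixes per-species DM
yields — "low yield" keeps the business-as-usual 5.7 t/ha for every grass,
"high yield" uses each species' highest reported yield (Buffel 16, Napier
30, Rhodes 18 t/ha).  Pasture cells are allocated to the forage species
maximising suitability x yield; cells suitable for none go to "other
grasses" at 5.7 t/ha.  Contribution % = 100 x supply / demand, reported
with the +/-28% yield-spread band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import RegionMask, SuitabilitySurface, cell_area_grid

__all__ = [
    "BreedProfile",
    "HerdScenario",
    "RegionHerd",
    "LandScenario",
    "ManagementScenario",
    "Allocation",
    "FeedBalanceReport",
    "LOCAL",
    "EXOTIC",
    "SCENARIO_A",
    "SCENARIO_B",
    "LAND_CURRENT",
    "LAND_2050",
    "MGMT_LOW_YIELD",
    "MGMT_HIGH_YIELD",
    "OTHER_GRASS_YIELD",
    "SPECIES_ORDER",
    "annual_dm_per_head",
    "herd_demand",
    "demand_increase_ratio",
    "pasture_area_ha",
    "species_contribution",
    "allocate_best",
    "feed_balance",
    "read_herd_csv",
]

KM2_TO_HA = 100.0

#: fixed species order used for deterministic tie-breaking
SPECIES_ORDER = ("Buffel", "Napier", "Rhodes")

OTHER_GRASS_YIELD = 5.7  # t DM / ha / yr, average of non-modelled grasses


@dataclass(frozen=True)
class BreedProfile:
    name: str
    live_weight_kg: float
    intake_fraction: float = 0.025  # of body weight per day
    days_per_year: int = 365

    def __post_init__(self) -> None:
        if self.live_weight_kg <= 0:
            raise ValueError("live weight must be positive")
        if not (0.0 < self.intake_fraction < 1.0):
            raise ValueError("intake fraction must be in (0, 1)")


LOCAL = BreedProfile("local", 200.0)
EXOTIC = BreedProfile("exotic", 600.0)


@dataclass(frozen=True)
class HerdScenario:
    """Breed mix: fractions of local and exotic head, summing to 1."""

    label: str
    f_local: float
    f_exotic: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_local <= 1.0 and 0.0 <= self.f_exotic <= 1.0):
            raise ValueError("breed fractions must lie in [0, 1]")
        if abs(self.f_local + self.f_exotic - 1.0) > 1e-12:
            raise ValueError("breed fractions must sum to 1")


SCENARIO_A = HerdScenario("A", 0.93, 0.07)
SCENARIO_B = HerdScenario("B", 0.60, 0.40)


@dataclass(frozen=True)
class RegionHerd:
    region: str
    n_cattle: int

    def __post_init__(self) -> None:
        if self.n_cattle < 0:
            raise ValueError("head count must be nonnegative")


@dataclass(frozen=True)
class LandScenario:
    """Fraction of a region's total land available as pasture."""

    pasture_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pasture_fraction <= 1.0):
            raise ValueError("pasture fraction must be in (0, 1]")


LAND_CURRENT = LandScenario(0.15)
LAND_2050 = LandScenario(0.10)


@dataclass(frozen=True)
class ManagementScenario:
    """Per-species DM yields (t/ha/yr) under one management regime."""

    label: str
    yields_t_per_ha: Mapping[str, float]
    other_grass_yield: float = OTHER_GRASS_YIELD

    def __post_init__(self) -> None:
        if any(y <= 0 for y in self.yields_t_per_ha.values()):
            raise ValueError("yields must be positive")
        object.__setattr__(self, "yields_t_per_ha", dict(self.yields_t_per_ha))


MGMT_LOW_YIELD = ManagementScenario(
    "F(LY)", {"Buffel": 5.7, "Napier": 5.7, "Rhodes": 5.7}
)
MGMT_HIGH_YIELD = ManagementScenario(
    "F(HY)", {"Buffel": 16.0, "Napier": 30.0, "Rhodes": 18.0}
)


def annual_dm_per_head(breed: BreedProfile) -> float:
    """Metric tons of dry matter one head requires per year."""
    return breed.live_weight_kg * breed.intake_fraction * breed.days_per_year / 1000.0


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def herd_demand(
    herd: RegionHerd,
    scenario: HerdScenario,
    local: BreedProfile = LOCAL,
    exotic: BreedProfile = EXOTIC,
) -> int:
    """Annual DM demand of one region's herd, whole metric tons."""
    per_head = (
        scenario.f_local * annual_dm_per_head(local)
        + scenario.f_exotic * annual_dm_per_head(exotic)
    )
    return _round_half_away(herd.n_cattle * per_head)


def demand_increase_ratio(
    scenario_a: HerdScenario,
    scenario_b: HerdScenario,
    local: BreedProfile = LOCAL,
    exotic: BreedProfile = EXOTIC,
) -> int:
    """Per-head demand of scenario B as a whole percent of scenario A."""
    def per_head(s: HerdScenario) -> float:
        return s.f_local * annual_dm_per_head(local) + s.f_exotic * annual_dm_per_head(
            exotic
        )

    return _round_half_away(100.0 * per_head(scenario_b) / per_head(scenario_a))


def pasture_area_ha(
    region_area_ha: float, land: LandScenario, suitable_fraction: float
) -> float:
    """Hectares of suitable pasture: region x pasture fraction x suitability %."""
    if region_area_ha < 0:
        raise ValueError("region area must be nonnegative")
    if not (0.0 <= suitable_fraction <= 100.0):
        raise ValueError("suitable fraction is a percent in [0, 100]")
    return region_area_ha * land.pasture_fraction * suitable_fraction / 100.0


def species_contribution(area_ha: float, yield_t_per_ha: float, demand_t: float) -> float:
    """Percent of demand met by one species grown on a given area."""
    if demand_t <= 0:
        raise ValueError("demand must be positive")
    return 100.0 * area_ha * yield_t_per_ha / demand_t


@dataclass(frozen=True)
class Allocation:
    """Pasture areas (ha) assigned per species plus the other-grass remainder."""

    region: str
    areas_ha: dict[str, float]
    other_grass_ha: float
    pasture_fraction: float

    @property
    def total_ha(self) -> float:
        return sum(self.areas_ha.values()) + self.other_grass_ha


def allocate_best(
    surfaces: Mapping[str, SuitabilitySurface],
    mask: RegionMask,
    region_id: int,
    land: LandScenario,
    mgmt: ManagementScenario,
    threshold: float = 40.0,
    species_order: Sequence[str] = SPECIES_ORDER,
) -> Allocation:
    """Assign each pasture cell to the forage maximising score x yield.

    A cell is eligible if any species meets the suitability threshold there;
    among the species meeting it, the one with the largest score x yield
    wins (ties: higher raw score, then the fixed species order).  Ineligible
    cells go to "other grasses".  Cell areas are scaled by the land
    scenario's pasture fraction.
    """
    order = [s for s in species_order if s in surfaces] + [
        s for s in surfaces if s not in species_order
    ]
    spec = None
    for s in order:
        if spec is None:
            spec = surfaces[s].spec
        elif surfaces[s].spec != spec:
            raise ValueError("species surfaces are on different grids")
    assert spec is not None
    if mask.spec != spec:
        raise ValueError("region mask grid does not match surfaces")
    region = mask.cells(region_id)
    valid = region.copy()
    for s in order:
        valid &= surfaces[s].valid_mask()
    w_ha = cell_area_grid(spec) * KM2_TO_HA * land.pasture_fraction

    scores = np.stack([surfaces[s].scores for s in order])  # (k, r, c)
    yields = np.array([mgmt.yields_t_per_ha[s] for s in order])
    meets = scores >= threshold
    eligible = valid & np.any(meets, axis=0)
    utility = np.where(meets, scores * yields[:, None, None], -np.inf)
    # argmax with ties broken by raw score then species order: lexicographic
    # key (utility, score, -index); np.lexsort is overkill — do it in two
    # passes since k is tiny.
    best_idx = np.zeros(scores.shape[1:], dtype=np.int64)
    best_util = np.full(scores.shape[1:], -np.inf)
    best_score = np.full(scores.shape[1:], -np.inf)
    for i in range(len(order)):
        u, sc = utility[i], scores[i]
        better = (u > best_util) | ((u == best_util) & (sc > best_score))
        best_idx = np.where(better, i, best_idx)
        best_score = np.where(better, sc, best_score)
        best_util = np.where(better, u, best_util)
    areas = {}
    for i, s in enumerate(order):
        sel = eligible & (best_idx == i)
        areas[s] = float(np.sum(w_ha[sel]))
    other = float(np.sum(w_ha[valid & ~eligible]))
    return Allocation(
        region=mask.names.get(region_id, str(region_id)),
        areas_ha=areas,
        other_grass_ha=other,
        pasture_fraction=land.pasture_fraction,
    )


@dataclass(frozen=True)
class FeedBalanceReport:
    """Per-region supply vs demand with per-species contributions."""

    region: str
    demand_t: float
    areas_ha: dict[str, float]
    supply_t: dict[str, float]
    contribution_pct: dict[str, float]
    other_grass_supply_t: float
    other_grass_pct: float
    total_contribution_pct: float
    surplus_pct: float  # total - 100; negative = deficit
    uncertainty_band_pct: float = 28.0

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"region": self.region, "demand_t": self.demand_t}
        for s in self.areas_ha:
            row[f"{s}_area_ha"] = self.areas_ha[s]
            row[f"{s}_supply_t"] = self.supply_t[s]
            row[f"{s}_contribution_pct"] = self.contribution_pct[s]
        row["other_grass_supply_t"] = self.other_grass_supply_t
        row["other_grass_pct"] = self.other_grass_pct
        row["total_contribution_pct"] = self.total_contribution_pct
        row["surplus_pct"] = self.surplus_pct
        row["band_pct"] = self.uncertainty_band_pct
        return row


def feed_balance(
    allocation: Allocation,
    mgmt: ManagementScenario,
    demand_t: float,
    band_pct: float = 28.0,
) -> FeedBalanceReport:
    """Supply, per-species contribution % and surplus/deficit for one region."""
    if demand_t <= 0:
        raise ValueError("demand must be positive")
    supply = {
        s: a * mgmt.yields_t_per_ha[s] for s, a in allocation.areas_ha.items()
    }
    contrib = {s: 100.0 * v / demand_t for s, v in supply.items()}
    other_supply = allocation.other_grass_ha * mgmt.other_grass_yield
    other_pct = 100.0 * other_supply / demand_t
    total = sum(contrib.values()) + other_pct
    return FeedBalanceReport(
        region=allocation.region,
        demand_t=demand_t,
        areas_ha=dict(allocation.areas_ha),
        supply_t=supply,
        contribution_pct=contrib,
        other_grass_supply_t=other_supply,
        other_grass_pct=other_pct,
        total_contribution_pct=total,
        surplus_pct=total - 100.0,
        uncertainty_band_pct=band_pct,
    )


def read_herd_csv(path) -> pd.DataFrame:
    """Read a herd table CSV with columns region, n_cattle[, area_ha]."""
    df = pd.read_csv(path)
    required = {"region", "n_cattle"}
    if not required.issubset(df.columns):
        raise ValueError(f"herd CSV must have columns {sorted(required)}")
    return df
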