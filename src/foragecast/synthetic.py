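"""Self-contained synthetic inputs mimicking East-African monthly climate.

The generator produces what the analysis pipeline expects from gridded
climate archives, with the same statistical structure but no downloads:

* a current-climate stack of 12 monthly tmin/tmax/prec layers on a 5
  arc-minute lon/lat grid, with an elevation-like smooth temperature field
  and a single unimodal wet season peaking in July-August (monthly totals
  kept below a 350 mm cap, as observed in the wettest parts of the study
  area);
* four rectangular pseudo-regions stacked north to south whose annual
  rainfall regimes span the ranges reported for Tigray (450-980 mm),
  Amhara (850-1485 mm), Oromia (410-2000 mm) and SNNP (500-2200 mm);
* future stacks for three GCM-like warming scenarios (+1.96, +2.36,
  +2.93 deg C mean annual warming) with configurable monthly precipitation
  deltas (default: July-August drying of 30 mm/month under the single-model
  scenarios, mild wetting under the ensemble mean);
* crop-parameter sets for Buffel, Napier and Rhodes grass consistent with
  their published temperature and annual-rainfall ranges;
* a herd table with the regional dairy-cattle head counts used in the
  feed-demand scenarios.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .ecocrop import CropParameters
from .raster import ClimateStack, GridSpec, RegionMask, cell_area_km2, apply_delta

__all__ = [
    "SyntheticConfig",
    "PlantedFixture",
    "generate_current",
    "generate_future",
    "default_crop_parameters",
    "default_herd_table",
    "planted_fraction_fixture",
    "DEFAULT_WARMING",
    "DEFAULT_PRECIP_DELTAS",
]

#: mean annual warming (deg C) of the three GCM-like 2050 scenarios
DEFAULT_WARMING: dict[str, float] = {
    "GISS-E2-R": 1.96,
    "ENSEMBLE-17GCM": 2.36,
    "HadGEM2-ES": 2.93,
}

#: default monthly precipitation deltas (mm), 0-based month -> shift
DEFAULT_PRECIP_DELTAS: dict[str, dict[int, float]] = {
    "GISS-E2-R": {6: -30.0, 7: -30.0},
    "ENSEMBLE-17GCM": {6: 10.0, 7: 10.0},
    "HadGEM2-ES": {6: -30.0, 7: -30.0},
}

#: (name, annual rainfall range mm) of the pseudo-regions, listed north to south
_REGION_BANDS: tuple[tuple[str, float, float], ...] = (
    ("Tigray", 450.0, 980.0),
    ("Amhara", 850.0, 1485.0),
    ("Oromia", 410.0, 2000.0),
    ("SNNP", 500.0, 2200.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic climate world.

    The grid defaults to a 5 arc-minute window over the Ethiopian
    highlands' latitude span; ``n_rows`` must be divisible by the number of
    pseudo-regions (4).
    """

    n_rows: int = 48
    n_cols: int = 60
    cell_size: float = 1.0 / 12.0
    west: float = 36.0
    north: float = 15.0
    seed: int = 0
    #: temperature drop (deg C) from the lowest to the highest pseudo-elevation
    #: (~2500 m of relief at a 6.5 deg C/km lapse rate)
    elevation_gradient_c: float = 16.0
    #: annual-mean near-surface temperature of the warmest lowlands, deg C
    base_temperature_c: float = 27.0
    #: amplitude of the seasonal temperature cycle, deg C
    seasonal_amplitude_c: float = 2.0
    #: diurnal range tmax - tmin, deg C
    diurnal_range_c: float = 12.0
    #: wet season peaks midway through July-August (1-based month 7.5)
    wet_season_center: float = 7.5
    #: monthly rainfall cap, mm ("< 350 mm in the wettest regions")
    monthly_cap_mm: float = 350.0
    warming_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WARMING)
    )
    precip_deltas: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PRECIP_DELTAS.items()}
    )
    #: amplitude of spatially correlated noise added to future deltas, deg C
    delta_noise_c: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_rows % 4:
            raise ValueError("n_rows must be a positive multiple of 4")
        if self.n_cols < 1:
            raise ValueError("n_cols must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
            west=self.west,
            north=self.north,
        )


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """Smooth random surface in [0, 1]: a few random-phase sinusoids."""
    y, x = np.meshgrid(
        np.linspace(0.0, 1.0, n_rows), np.linspace(0.0, 1.0, n_cols), indexing="ij"
    )
    f = np.zeros((n_rows, n_cols))
    for _ in range(6):
        fx, fy = rng.uniform(0.5, 3.0, size=2)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.sin(2.0 * math.pi * (fx * x + fy * y) + phase)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def _wet_season_weights(annual_mm: np.ndarray, center: float) -> np.ndarray:
    """(12, ...) monthly shares of the annual total, unimodal around July-Aug.

    The season widens with annual total (wetter climates have longer wet
    seasons), which also keeps peak months under the monthly cap.
    """
    months = np.arange(1, 13, dtype=np.float64)
    sigma = 1.6 + 1.2 * np.clip(annual_mm / 2200.0, 0.0, 1.5)
    w = np.exp(
        -((months[:, None, None] - center) ** 2) / (2.0 * sigma[None, :, :] ** 2)
    )
    return w / np.sum(w, axis=0)


def generate_current(config: SyntheticConfig) -> tuple[ClimateStack, RegionMask]:
    """Synthesize the current-climate stack and its four-region mask."""
    spec = config.grid
    nr, nc = config.n_rows, config.n_cols
    rng = np.random.default_rng(config.seed)

    # elevation-like surface drives a smooth temperature gradient
    elev = _smooth_field(rng, nr, nc)
    tavg_annual = config.base_temperature_c - config.elevation_gradient_c * elev

    months = np.arange(12)
    # warmest just before the rains (around April), mild seasonality
    cycle = config.seasonal_amplitude_c * np.cos(2.0 * math.pi * (months - 3) / 12.0)
    tavg = tavg_annual[None, :, :] + cycle[:, None, None]
    half_range = config.diurnal_range_c / 2.0
    tmin = tavg - half_range
    tmax = tavg + half_range

    # region bands north -> south with distinct annual rainfall regimes
    ids = np.zeros((nr, nc), dtype=np.int32)
    annual = np.zeros((nr, nc))
    band_rows = nr // 4
    names: dict[int, str] = {}
    lon01 = np.linspace(0.0, 1.0, nc)[None, :]
    wetness_noise = 0.1 * (_smooth_field(rng, nr, nc) - 0.5)
    for i, (name, lo, hi) in enumerate(_REGION_BANDS):
        rid = i + 1
        names[rid] = name
        rows = slice(i * band_rows, (i + 1) * band_rows)
        ids[rows, :] = rid
        frac = np.clip(lon01 + wetness_noise[rows, :], 0.0, 1.0)
        annual[rows, :] = lo + (hi - lo) * frac

    weights = _wet_season_weights(annual, config.wet_season_center)
    prec = np.minimum(weights * annual[None, :, :], config.monthly_cap_mm)

    stack = ClimateStack(spec=spec, tmin=tmin, tmax=tmax, prec=prec)
    mask = RegionMask(spec=spec, ids=ids, names=names)
    return stack, mask


def generate_future(
    stack: ClimateStack, scenario_label: str, config: SyntheticConfig
) -> ClimateStack:
    """Warm a current stack by one scenario's offsets.

    Temperature rises uniformly by the configured mean annual offset (plus
    optional zero-mean spatially correlated noise, so the area-mean warming
    stays exact); monthly precipitation deltas are additive mm, floored at
    zero downstream.
    """
    if scenario_label not in config.warming_offsets:
        raise KeyError(
            f"unknown scenario {scenario_label!r}; "
            f"known: {sorted(config.warming_offsets)}"
        )
    offset = float(config.warming_offsets[scenario_label])
    nr, nc = stack.spec.n_rows, stack.spec.n_cols
    if config.delta_noise_c > 0.0:
        rng = np.random.default_rng(
            (config.seed * 1000003 + abs(hash(scenario_label)) % 65521) % 2**31
        )
        noise = _smooth_field(rng, nr, nc)
        noise = noise - noise.mean()  # zero mean: area-mean warming is exact
        delta_t = offset + config.delta_noise_c * noise
    else:
        delta_t = np.full((nr, nc), offset)
    dp = np.zeros(12)
    for m, shift in config.precip_deltas.get(scenario_label, {}).items():
        dp[int(m)] = shift
    return apply_delta(stack, delta_t=delta_t[None, :, :], delta_p=dp, precip_mode="mm")


def default_crop_parameters() -> list[CropParameters]:
    """Parameter sets for Buffel, Napier and Rhodes grass.

    Cardinal temperatures follow the published growth ranges (Buffel
    optimal 30-35 deg C; Napier grows at 21-40 deg C; Rhodes at 20-37 deg C).
    Growing-season rainfall thresholds are the published annual ranges
    scaled by g_used/12 (a 4- or 5-month season receives that share of the
    annual total).
    """

    def seasonal(annual: tuple[float, float, float, float], g: int):
        return tuple(round(a * g / 12.0) for a in annual)

    buffel_r = seasonal((270.0, 600.0, 1800.0, 3500.0), 4)
    napier_r = seasonal((700.0, 1000.0, 2500.0, 4000.0), 5)
    rhodes_r = seasonal((300.0, 600.0, 1500.0, 2200.0), 4)
    return [
        CropParameters(
            species_name="Buffel",
            g_used=4,
            ktmp=2.0,
            t_min=12.0,
            t_opmin=30.0,
            t_opmax=35.0,
            t_max=45.0,
            r_min=buffel_r[0],
            r_opmin=buffel_r[1],
            r_opmax=buffel_r[2],
            r_max=buffel_r[3],
        ),
        CropParameters(
            species_name="Napier",
            g_used=5,
            ktmp=6.0,
            t_min=15.0,
            t_opmin=21.0,
            t_opmax=35.0,
            t_max=40.0,
            r_min=napier_r[0],
            r_opmin=napier_r[1],
            r_opmax=napier_r[2],
            r_max=napier_r[3],
        ),
        CropParameters(
            species_name="Rhodes",
            g_used=4,
            ktmp=2.0,
            t_min=20.0,
            t_opmin=25.0,
            t_opmax=30.0,
            t_max=37.0,
            r_min=rhodes_r[0],
            r_opmin=rhodes_r[1],
            r_opmax=rhodes_r[2],
            r_max=rhodes_r[3],
        ),
    ]


def default_herd_table() -> pd.DataFrame:
    """Regional dairy-cattle head counts from the national census."""
    return pd.DataFrame(
        {
            "region": ["Amhara", "Oromia", "Tigray", "SNNP"],
            "n_cattle": [14_710_911, 22_925_730, 4_578_181, 11_215_636],
        }
    )


class PlantedFixture(NamedTuple):
    """A constructed stack whose true suitable fraction is known exactly."""

    stack: ClimateStack
    mask: RegionMask
    region_id: int
    target_fraction: float
    achieved_fraction: float


def planted_fraction_fixture(
    target_fraction: float,
    params: CropParameters,
    config: SyntheticConfig,
    region_id: int = 1,
) -> PlantedFixture:
    """Construct a stack where a known area fraction of a region is optimal.

    Cells are planted in row-major order until the accumulated
    (latitude-weighted) area is as close as possible to the target percent
    of the region's area; planted cells get optimal temperature and
    rainfall, every other cell sits below t_min with zero rain.  The
    returned ``achieved_fraction`` is exact by construction (within one
    cell's area share of the target on any finite grid).
    """
    if not (0.0 <= target_fraction <= 100.0):
        raise ValueError("target fraction is a percent in [0, 100]")
    spec = config.grid
    nr, nc = spec.n_rows, spec.n_cols
    _, mask = generate_current(config)
    region = mask.cells(region_id)

    w = np.array([cell_area_km2(r, spec) for r in range(nr)])
    w_grid = np.repeat(w[:, None], nc, axis=1)
    region_total = float(np.sum(w_grid[region]))
    target_area = target_fraction / 100.0 * region_total

    planted = np.zeros((nr, nc), dtype=bool)
    acc = 0.0
    for r in range(nr):
        for c in range(nc):
            if not region[r, c]:
                continue
            if abs(acc + w_grid[r, c] - target_area) < abs(acc - target_area):
                planted[r, c] = True
                acc += w_grid[r, c]
    achieved = 100.0 * acc / region_total

    t_opt = (params.t_opmin + params.t_opmax) / 2.0
    t_bad = params.t_min - 5.0
    p_opt = (params.r_opmin + params.r_opmax) / 2.0 / params.g_used

    temp = np.where(planted, t_opt, t_bad)
    tmin = np.repeat(temp[None, :, :], 12, axis=0)
    tmax = tmin.copy()
    prec = np.where(planted, p_opt, 0.0)
    prec = np.repeat(prec[None, :, :], 12, axis=0)
    stack = ClimateStack(spec=spec, tmin=tmin, tmax=tmax, prec=prec)
    return PlantedFixture(stack, mask, region_id, target_fraction, achieved)
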