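"""Mechanistic per-cell climate suitability scoring (ECOCROP-style).

A crop is described by twelve thresholds: a growing-season length ``g_used``
(whole months), an absolute kill temperature ``ktmp``, four cardinal
temperatures (``t_min`` < ``t_opmin`` <= ``t_opmax`` < ``t_max``) and four
growing-season rainfall totals (``r_min`` < ``r_opmin`` <= ``r_opmax`` <
``r_max``).  For every candidate start month (all twelve, wrapping across the
year boundary) the season is scored:

* temperature — the minimum over the season's months of a trapezoidal
  membership of the monthly temperature against the cardinal temperatures,
  evaluated twice, once on the monthly-mean-minimum series and once on the
  monthly-mean-maximum series;
* kill rule — if any season month's mean minimum falls strictly below
  ``ktmp`` the season scores 0;
* rainfall — a single trapezoidal membership of the season's total
  precipitation against the rainfall thresholds.

Per season the temperature and rainfall scores are combined (product by
default), and the tmin-driven and tmax-driven results are merged by a
piecewise ratio-of-squares rule; the cell's suitability is the best season.
Scores are percentages in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "CropParameters",
    "CellClimate",
    "SeasonEvaluation",
    "SuitabilityClass",
    "SuitabilityScore",
    "trapezoid_score",
    "kill_applies",
    "season_temp_suitability",
    "season_rain_suitability",
    "combine_total",
    "cell_suitability",
    "evaluate_seasons",
    "classify_score",
    "read_crop_csv",
    "write_crop_csv",
]

SeasonCombiner = Literal["product", "min"]


class ParameterError(ValueError):
    """Raised when crop thresholds violate their required ordering."""


@dataclass(frozen=True)
class CropParameters:
    """Growth, temperature and rainfall thresholds for one species.

    Temperatures in deg C, rainfall totals in mm over the growing season,
    ``g_used`` in whole months (1-12).  ``g_min``/``g_max`` optionally
    restrict the candidate start months to a calendar window.
    """

    species_name: str
    g_used: int
    ktmp: float
    t_min: float
    t_opmin: float
    t_opmax: float
    t_max: float
    r_min: float
    r_opmin: float
    r_opmax: float
    r_max: float
    g_min: int | None = None
    g_max: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= int(self.g_used) <= 12):
            raise ParameterError(f"g_used must be 1..12 months, got {self.g_used}")
        if not (self.ktmp <= self.t_min < self.t_opmin <= self.t_opmax < self.t_max):
            raise ParameterError(
                f"temperature thresholds must satisfy "
                f"ktmp <= t_min < t_opmin <= t_opmax < t_max for {self.species_name}"
            )
        if not (self.r_min < self.r_opmin <= self.r_opmax < self.r_max):
            raise ParameterError(
                f"rainfall thresholds must satisfy "
                f"r_min < r_opmin <= r_opmax < r_max for {self.species_name}"
            )
        for g in (self.g_min, self.g_max):
            if g is not None and not (1 <= int(g) <= 12):
                raise ParameterError(f"calendar window bounds must be 1..12, got {g}")

    def start_months(self) -> list[int]:
        """Candidate season start months (1-based), honouring g_min/g_max."""
        if self.g_min is None or self.g_max is None:
            return list(range(1, 13))
        lo, hi = int(self.g_min), int(self.g_max)
        if lo <= hi:
            return list(range(lo, hi + 1))
        # window wraps across the year boundary
        return list(range(lo, 13)) + list(range(1, hi + 1))

    @staticmethod
    def growing_days_to_months(days: float) -> int:
        """Convert a growing-period length in days to whole months (>= 1)."""
        return max(1, int(round(days / 30.0)))


@dataclass(frozen=True)
class CellClimate:
    """Twelve-month climate for one grid cell.

    ``tavg`` is derived as (tmin + tmax) / 2 unless supplied.
    """

    tmin: tuple[float, ...]
    tmax: tuple[float, ...]
    prec: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "prec"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 12:
                raise ValueError(f"{name} must have 12 monthly values")
            object.__setattr__(self, name, vals)
        if any(a > b for a, b in zip(self.tmin, self.tmax)):
            raise ValueError("tmin must not exceed tmax in any month")
        if any(p < 0 for p in self.prec):
            raise ValueError("precipitation must be non-negative")

    @property
    def tavg(self) -> tuple[float, ...]:
        return tuple((a + b) / 2.0 for a, b in zip(self.tmin, self.tmax))


class SuitabilityClass(str, Enum):
    UNSUITABLE = "unsuitable"
    VERY_MARGINAL = "very marginal"
    MARGINAL = "marginal"
    SUITABLE = "suitable"
    VERY_SUITABLE = "very suitable"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class SuitabilityScore:
    value: float
    label: SuitabilityClass = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", classify_score(self.value))


@dataclass(frozen=True)
class SeasonEvaluation:
    """Scores for one candidate growing season of one cell."""

    start_month: int
    killed: bool
    temp_suit_min: float
    temp_suit_max: float
    rain_suit: float
    combined: float


def trapezoid_score(
    x: float, lo: float, opt_lo: float, opt_hi: float, hi: float
) -> float:
    """Trapezoidal membership on a 0-100 scale.

    0 outside (lo, hi), 100 on [opt_lo, opt_hi], linear on the shoulders.
    """
    if not (lo < opt_lo <= opt_hi < hi):
        raise ParameterError(
            f"trapezoid thresholds must satisfy lo < opt_lo <= opt_hi < hi, "
            f"got ({lo}, {opt_lo}, {opt_hi}, {hi})"
        )
    if x <= lo or x >= hi:
        return 0.0
    if opt_lo <= x <= opt_hi:
        return 100.0
    if x < opt_lo:
        return 100.0 * (x - lo) / (opt_lo - lo)
    return 100.0 * (hi - x) / (hi - opt_hi)


def kill_applies(tmin_month: float, ktmp: float) -> bool:
    """Kill rule: monthly mean minimum strictly below the kill temperature."""
    return tmin_month < ktmp


def _season_months(start_month: int, g_used: int) -> list[int]:
    """0-based month indices of a season, wrapping December -> January."""
    return [(start_month - 1 + k) % 12 for k in range(g_used)]


def season_temp_suitability(
    cell: CellClimate,
    start_month: int,
    params: CropParameters,
    series: Literal["min", "max", "avg"] = "min",
    ktmp_offset: float = 0.0,
) -> float:
    """Temperature score of one season: 0 on kill, else the worst month.

    The kill rule always reads the tmin series; ``series`` selects which
    monthly temperatures feed the trapezoid.
    """
    months = _season_months(start_month, params.g_used)
    if any(kill_applies(cell.tmin[m] - ktmp_offset, params.ktmp) for m in months):
        return 0.0
    data = {"min": cell.tmin, "max": cell.tmax, "avg": cell.tavg}[series]
    return min(
        trapezoid_score(
            data[m], params.t_min, params.t_opmin, params.t_opmax, params.t_max
        )
        for m in months
    )


def season_rain_suitability(
    cell: CellClimate, start_month: int, params: CropParameters
) -> float:
    """Rainfall score of one season from the season's total precipitation."""
    months = _season_months(start_month, params.g_used)
    total = sum(cell.prec[m] for m in months)
    return trapezoid_score(
        total, params.r_min, params.r_opmin, params.r_opmax, params.r_max
    )


def combine_total(s_min_r: float, s_max_r: float) -> float:
    """Merge the tmin-driven and tmax-driven season scores.

    Piecewise: the nonzero one if the other is zero, the ratio of the sum of
    squares to the sum when both are nonzero, and 0 when both are zero.
    """
    if s_min_r == 0.0 and s_max_r == 0.0:
        return 0.0
    if s_max_r == 0.0:
        return s_min_r
    if s_min_r == 0.0:
        return s_max_r
    # explicit multiplication (not **2) so scalar and vectorised paths agree
    # to the last bit
    return (s_min_r * s_min_r + s_max_r * s_max_r) / (s_min_r + s_max_r)


def evaluate_seasons(
    cell: CellClimate,
    params: CropParameters,
    season_combiner: SeasonCombiner = "product",
    ktmp_offset: float = 0.0,
) -> list[SeasonEvaluation]:
    """Score every candidate growing season of one cell."""
    out: list[SeasonEvaluation] = []
    for start in params.start_months():
        months = _season_months(start, params.g_used)
        killed = any(
            kill_applies(cell.tmin[m] - ktmp_offset, params.ktmp) for m in months
        )
        t_min_s = season_temp_suitability(cell, start, params, "min", ktmp_offset)
        t_max_s = season_temp_suitability(cell, start, params, "max", ktmp_offset)
        rain = season_rain_suitability(cell, start, params)
        if killed:
            combined = 0.0
        else:
            if season_combiner == "product":
                s_min_r = t_min_s * rain / 100.0
                s_max_r = t_max_s * rain / 100.0
            elif season_combiner == "min":
                s_min_r = min(t_min_s, rain)
                s_max_r = min(t_max_s, rain)
            else:
                raise ValueError(f"unknown season_combiner {season_combiner!r}")
            combined = combine_total(s_min_r, s_max_r)
        out.append(
            SeasonEvaluation(
                start_month=start,
                killed=killed,
                temp_suit_min=t_min_s,
                temp_suit_max=t_max_s,
                rain_suit=rain,
                combined=combined,
            )
        )
    return out


def cell_suitability(
    cell: CellClimate,
    params: CropParameters,
    season_combiner: SeasonCombiner = "product",
    ktmp_offset: float = 0.0,
) -> SuitabilityScore:
    """Best combined score over all candidate start months."""
    seasons = evaluate_seasons(cell, params, season_combiner, ktmp_offset)
    return SuitabilityScore(max(s.combined for s in seasons))


def classify_score(value: float) -> SuitabilityClass:
    """Map a 0-100 score to its class label.

    0 -> unsuitable, (0,20] very marginal, (20,40] marginal, (40,60]
    suitable, (60,80] very suitable, (80,100] excellent.
    """
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"score must be in [0, 100], got {value}")
    if value == 0.0:
        return SuitabilityClass.UNSUITABLE
    if value <= 20.0:
        return SuitabilityClass.VERY_MARGINAL
    if value <= 40.0:
        return SuitabilityClass.MARGINAL
    if value <= 60.0:
        return SuitabilityClass.SUITABLE
    if value <= 80.0:
        return SuitabilityClass.VERY_SUITABLE
    return SuitabilityClass.EXCELLENT


# Crop-parameter CSV interface.  Column names follow the conventional
# ECOCROP field names; Gused may be given in days (gused_unit column or
# values > 12 flagged via the `gused_unit` argument).
_CSV_COLUMNS = [
    "species",
    "Gmin",
    "Gmax",
    "Gused",
    "KTMP",
    "Tmin",
    "TOpmn",
    "TOpmx",
    "Tmax",
    "Rmin",
    "ROpmin",
    "ROpmax",
    "Rmax",
]


def read_crop_csv(
    path: str | Path, gused_unit: Literal["months", "days"] = "months"
) -> list[CropParameters]:
    """Read crop parameter sets from CSV (columns Gmin..Rmax)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"crop CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        g = float(row["Gused"])
        g_used = (
            CropParameters.growing_days_to_months(g) if gused_unit == "days" else int(g)
        )
        def _window(v: object) -> int | None:
            return None if pd.isna(v) else int(v)
        out.append(
            CropParameters(
                species_name=str(row["species"]),
                g_used=g_used,
                g_min=_window(row["Gmin"]),
                g_max=_window(row["Gmax"]),
                ktmp=float(row["KTMP"]),
                t_min=float(row["Tmin"]),
                t_opmin=float(row["TOpmn"]),
                t_opmax=float(row["TOpmx"]),
                t_max=float(row["Tmax"]),
                r_min=float(row["Rmin"]),
                r_opmin=float(row["ROpmin"]),
                r_opmax=float(row["ROpmax"]),
                r_max=float(row["Rmax"]),
            )
        )
    return out


def write_crop_csv(params: Iterable[CropParameters], path: str | Path) -> None:
    rows = []
    for p in params:
        rows.append(
            {
                "species": p.species_name,
                "Gmin": p.g_min if p.g_min is not None else "",
                "Gmax": p.g_max if p.g_max is not None else "",
                "Gused": p.g_used,
                "KTMP": p.ktmp,
                "Tmin": p.t_min,
                "TOpmn": p.t_opmin,
                "TOpmx": p.t_opmax,
                "Tmax": p.t_max,
                "Rmin": p.r_min,
                "ROpmin": p.r_opmin,
                "ROpmax": p.r_opmax,
                "Rmax": p.r_max,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
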