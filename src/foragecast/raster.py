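"""Gridded climate stacks, suitability surfaces and zonal area statistics.

Rasters live on a regular geographic (WGS84 lon/lat) grid with cell-center
registration and row 0 at the north.  On disk every layer is an ESRI ASCII
grid (``.asc``) — a plain-text format of six header lines followed by the
cell values — so climate stacks are directories of twelve ``tmin_MM.asc``,
``tmax_MM.asc`` and ``prec_MM.asc`` files.

Area statistics weight each cell by its spherical-Earth area, which shrinks
with the cosine of latitude; "suitable area" percentages are therefore true
area fractions, not cell counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .ecocrop import CropParameters, SeasonCombiner

__all__ = [
    "GridSpec",
    "ClimateStack",
    "SuitabilitySurface",
    "RegionMask",
    "NODATA",
    "EARTH_RADIUS_KM",
    "read_ascii_grid",
    "write_ascii_grid",
    "suitability_surface",
    "cell_area_km2",
    "cell_area_grid",
    "suitable_area_fraction",
    "suitability_shift",
    "apply_delta",
]

logger = logging.getLogger(__name__)

NODATA = -9999.0
EARTH_RADIUS_KM = 6371.0

#: default grid resolution, 5 arc-minutes (~9 km at the Equator)
FIVE_ARCMIN = 1.0 / 12.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: shape, cell size (decimal degrees), NW origin."""

    n_rows: int
    n_cols: int
    cell_size: float = FIVE_ARCMIN
    west: float = 0.0
    north: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if not (-180.0 <= self.west <= 180.0 and -90.0 <= self.north <= 90.0):
            raise ValueError("origin outside geographic bounds")
        if self.north - self.n_rows * self.cell_size < -90.0 - 1e-9:
            raise ValueError("grid extends south of -90 deg latitude")

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    def lat_center(self, row: int) -> float:
        return self.north - (row + 0.5) * self.cell_size

    def lat_edges(self, row: int) -> tuple[float, float]:
        """(top, bottom) latitude edges of a row."""
        return (
            self.north - row * self.cell_size,
            self.north - (row + 1) * self.cell_size,
        )


def cell_area_km2(row: int, spec: GridSpec) -> float:
    """Spherical-Earth area (km^2) of one cell at a given row.

    Area of the spherical zone slice: (pi/180) * R^2 * dlon_deg *
    |sin(lat_top) - sin(lat_bottom)|.
    """
    if not (0 <= row < spec.n_rows):
        raise IndexError(f"row {row} outside grid of {spec.n_rows} rows")
    top, bot = spec.lat_edges(row)
    return (
        (math.pi / 180.0)
        * EARTH_RADIUS_KM**2
        * spec.cell_size
        * abs(math.sin(math.radians(top)) - math.sin(math.radians(bot)))
    )


def cell_area_grid(spec: GridSpec) -> np.ndarray:
    """(n_rows, n_cols) array of cell areas in km^2."""
    col = np.array([cell_area_km2(r, spec) for r in range(spec.n_rows)])
    return np.repeat(col[:, None], spec.n_cols, axis=1)


@dataclass(frozen=True)
class ClimateStack:
    """12-month tmin/tmax/prec fields on one grid; nodata-aware."""

    spec: GridSpec
    tmin: np.ndarray  # (12, n_rows, n_cols), deg C
    tmax: np.ndarray
    prec: np.ndarray  # mm / month
    nodata: float = NODATA

    def __post_init__(self) -> None:
        shape = (12, self.spec.n_rows, self.spec.n_cols)
        for name in ("tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            object.__setattr__(self, name, arr)
        valid = self.valid_mask()
        if np.any(self.tmin[:, valid] > self.tmax[:, valid]):
            raise ValueError("tmin exceeds tmax in some valid cell-month")

    def valid_mask(self) -> np.ndarray:
        """(n_rows, n_cols) boolean: cells where all 36 layers carry data."""
        ok = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for arr in (self.tmin, self.tmax, self.prec):
            ok &= np.all(arr != self.nodata, axis=0)
        return ok

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, block in (("tmin", self.tmin), ("tmax", self.tmax), ("prec", self.prec)):
            for m in range(12):
                write_ascii_grid(
                    block[m], self.spec, path / f"{name}_{m + 1:02d}.asc", self.nodata
                )

    @classmethod
    def from_dir(cls, path: str | Path, nodata: float = NODATA) -> "ClimateStack":
        path = Path(path)
        blocks = {}
        spec = None
        for name in ("tmin", "tmax", "prec"):
            layers = []
            for m in range(12):
                arr, s = read_ascii_grid(path / f"{name}_{m + 1:02d}.asc")
                if spec is None:
                    spec = s
                elif s != spec:
                    raise ValueError(f"grid mismatch in {name} month {m + 1}")
                layers.append(arr)
            blocks[name] = np.stack(layers)
        assert spec is not None
        return cls(spec=spec, nodata=nodata, **blocks)


@dataclass(frozen=True)
class SuitabilitySurface:
    """Per-cell 0-100 suitability for one species under one climate."""

    spec: GridSpec
    scores: np.ndarray
    species_name: str = ""
    climate_label: str = ""
    nodata: float = NODATA

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=np.float64)
        if arr.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("scores shape does not match grid")
        valid = arr != self.nodata
        if np.any((arr[valid] < 0) | (arr[valid] > 100)):
            raise ValueError("scores must lie in [0, 100] or be nodata")
        object.__setattr__(self, "scores", arr)

    def valid_mask(self) -> np.ndarray:
        return self.scores != self.nodata

    def write(self, path: str | Path) -> None:
        write_ascii_grid(self.scores, self.spec, path, self.nodata)

    @classmethod
    def read(
        cls, path: str | Path, species_name: str = "", climate_label: str = ""
    ) -> "SuitabilitySurface":
        arr, spec = read_ascii_grid(path)
        return cls(spec, arr, species_name, climate_label)


@dataclass(frozen=True)
class RegionMask:
    """Integer region ids on the grid; 0 = outside every region."""

    spec: GridSpec
    ids: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.ids, dtype=np.int32)
        if arr.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("mask shape does not match grid")
        object.__setattr__(self, "ids", arr)

    def region_ids(self) -> list[int]:
        present = sorted(int(i) for i in np.unique(self.ids) if i != 0)
        return present

    def cells(self, region_id: int) -> np.ndarray:
        if region_id not in self.names and region_id not in self.region_ids():
            raise KeyError(f"unknown region id {region_id}")
        return self.ids == region_id

    def write(self, path: str | Path) -> None:
        write_ascii_grid(self.ids.astype(np.float64), self.spec, path, NODATA)


def write_ascii_grid(
    array: np.ndarray, spec: GridSpec, path: str | Path, nodata: float = NODATA
) -> None:
    """Write one layer as an ESRI ASCII grid (cell-corner xll/yll header)."""
    arr = np.asarray(array, dtype=np.float64)
    if arr.shape != (spec.n_rows, spec.n_cols):
        raise ValueError("array shape does not match grid spec")
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.west!r}\n")
        fh.write(f"yllcorner {spec.south!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in arr:
            fh.write(" ".join(repr(v) for v in row.tolist()) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (array, GridSpec)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value", "xllcenter", "yllcenter"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cs = header["cellsize"]
    west = header.get("xllcorner", header.get("xllcenter", 0.0) - cs / 2.0)
    south = header.get("yllcorner", header.get("yllcenter", 0.0) - cs / 2.0)
    arr = np.array([v for r in rows for v in r], dtype=np.float64).reshape(
        n_rows, n_cols
    )
    spec = GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=cs, west=west,
        north=south + n_rows * cs,
    )
    return arr, spec


def _trapezoid_grid(
    x: np.ndarray, lo: float, opt_lo: float, opt_hi: float, hi: float
) -> np.ndarray:
    """Vectorised trapezoid membership; mirrors the scalar rule exactly."""
    if not (lo < opt_lo <= opt_hi < hi):
        raise ValueError(
            f"trapezoid thresholds must satisfy lo < opt_lo <= opt_hi < hi, "
            f"got ({lo}, {opt_lo}, {opt_hi}, {hi})"
        )
    out = np.zeros_like(x)
    rising = (x > lo) & (x < opt_lo)
    out[rising] = 100.0 * (x[rising] - lo) / (opt_lo - lo)
    plateau = (x >= opt_lo) & (x <= opt_hi)
    out[plateau] = 100.0
    falling = (x > opt_hi) & (x < hi)
    out[falling] = 100.0 * (hi - x[falling]) / (hi - opt_hi)
    return out


def suitability_surface(
    stack: ClimateStack,
    params: CropParameters,
    season_combiner: SeasonCombiner = "product",
    ktmp_offset: float = 0.0,
    climate_label: str = "",
) -> SuitabilitySurface:
    """Apply the suitability engine to every cell of a climate stack.

    Vectorised over the grid; loops run over the 12 candidate seasons and
    their months in the same order as the per-cell evaluation, so the result
    is bit-identical to a cell-by-cell loop.
    """
    p = params
    shape = (stack.spec.n_rows, stack.spec.n_cols)
    best = np.zeros(shape)
    for start in p.start_months():
        months = [(start - 1 + k) % 12 for k in range(p.g_used)]
        killed = np.zeros(shape, dtype=bool)
        t_min_s = np.full(shape, np.inf)
        t_max_s = np.full(shape, np.inf)
        rain_total = np.zeros(shape)
        for m in months:
            killed |= (stack.tmin[m] - ktmp_offset) < p.ktmp
            t_min_s = np.minimum(
                t_min_s,
                _trapezoid_grid(stack.tmin[m], p.t_min, p.t_opmin, p.t_opmax, p.t_max),
            )
            t_max_s = np.minimum(
                t_max_s,
                _trapezoid_grid(stack.tmax[m], p.t_min, p.t_opmin, p.t_opmax, p.t_max),
            )
            rain_total = rain_total + stack.prec[m]
        rain = _trapezoid_grid(rain_total, p.r_min, p.r_opmin, p.r_opmax, p.r_max)
        t_min_s = np.where(killed, 0.0, t_min_s)
        t_max_s = np.where(killed, 0.0, t_max_s)
        if season_combiner == "product":
            s_min_r = t_min_s * rain / 100.0
            s_max_r = t_max_s * rain / 100.0
        elif season_combiner == "min":
            s_min_r = np.minimum(t_min_s, rain)
            s_max_r = np.minimum(t_max_s, rain)
        else:
            raise ValueError(f"unknown season_combiner {season_combiner!r}")
        denom = s_min_r + s_max_r
        both = (s_min_r != 0.0) & (s_max_r != 0.0)
        combined = np.where(s_max_r == 0.0, s_min_r, s_max_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = (s_min_r * s_min_r + s_max_r * s_max_r) / np.where(
                denom == 0.0, 1.0, denom
            )
        combined = np.where(both, ratio, combined)
        combined = np.where(killed, 0.0, combined)
        best = np.maximum(best, combined)
    valid = stack.valid_mask()
    scores = np.where(valid, best, stack.nodata)
    return SuitabilitySurface(
        spec=stack.spec,
        scores=scores,
        species_name=p.species_name,
        climate_label=climate_label,
        nodata=stack.nodata,
    )


def suitable_area_fraction(
    surface: SuitabilitySurface,
    mask: RegionMask,
    region_id: int,
    threshold: float = 40.0,
    inclusive: bool = True,
) -> float:
    """Percent of a region's area scoring at or above the threshold.

    Cells are weighted by spherical cell area; nodata cells are excluded
    from both numerator and denominator.
    """
    if mask.spec != surface.spec:
        raise ValueError("region mask and surface are on different grids")
    region = mask.cells(region_id)
    valid = region & surface.valid_mask()
    if not np.any(valid):
        raise ValueError(f"region {region_id} has no valid cells")
    w = cell_area_grid(surface.spec)
    if inclusive:
        suit = surface.scores >= threshold
    else:
        suit = surface.scores > threshold
    pct = 100.0 * float(np.sum(w[valid & suit])) / float(np.sum(w[valid]))
    # guard against float round-off just past the ends of the scale
    return min(max(pct, 0.0), 100.0)


def suitability_shift(current_pct: float, future_pct: float) -> float:
    """Loss (+) or gain (-) of suitable-area percentage under a future climate."""
    return current_pct - future_pct


def apply_delta(
    stack: ClimateStack,
    delta_t: float | np.ndarray = 0.0,
    delta_p: float | np.ndarray = 0.0,
    precip_mode: Literal["mm", "percent"] = "mm",
) -> ClimateStack:
    """Shift a climate stack by temperature/precipitation anomalies.

    ``delta_t`` adds to tmin and tmax (scalar, per-month (12,), or full
    field).  ``delta_p`` adds mm or scales by percent; negative resulting
    precipitation is clipped to zero (count logged).
    """
    dt = np.asarray(delta_t, dtype=np.float64)
    dp = np.asarray(delta_p, dtype=np.float64)

    def _expand(d: np.ndarray) -> np.ndarray:
        if d.ndim == 1:
            return d[:, None, None]
        return d

    dt = _expand(dt)
    dp = _expand(dp)
    valid = stack.valid_mask()
    tmin = np.where(valid, stack.tmin + dt, stack.tmin)
    tmax = np.where(valid, stack.tmax + dt, stack.tmax)
    if precip_mode == "mm":
        prec = stack.prec + dp
    elif precip_mode == "percent":
        prec = stack.prec * (1.0 + dp / 100.0)
    else:
        raise ValueError(f"unknown precip_mode {precip_mode!r}")
    clipped = int(np.sum((prec < 0) & valid))
    if clipped:
        logger.info("apply_delta: clipped %d negative precipitation cells to 0", clipped)
    prec = np.where(valid, np.maximum(prec, 0.0), stack.prec)
    return replace(stack, tmin=tmin, tmax=tmax, prec=prec)
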