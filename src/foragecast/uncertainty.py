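"""Cross-model agreement and prediction-uncertainty statistics.

Given a small ensemble of co-registered surfaces (suitability maps or
climate-shift fields from different general circulation models) this module
computes the cellwise spread (sample SD), a two-standard-deviation
significance flag within a region, region-standardised z-scores, and the
cellwise harmonic mean of three model surfaces.  A seeded Monte-Carlo
"R-factor" summarises prediction uncertainty of a set of observed values:
the sample SD of the observations times the 95% inter-quantile width of
normal resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import GridSpec, RegionMask, NODATA

__all__ = [
    "SurfaceEnsemble",
    "MonteCarloResult",
    "pixel_sd",
    "significance_2sd",
    "zscore_map",
    "harmonic_mean_surface",
    "rfactor_mc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurfaceEnsemble:
    """k >= 2 co-registered surfaces with model labels."""

    spec: GridSpec
    surfaces: np.ndarray  # (k, n_rows, n_cols)
    labels: tuple[str, ...]
    nodata: float = NODATA

    def __post_init__(self) -> None:
        arr = np.asarray(self.surfaces, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError("ensemble needs k >= 2 surfaces of shape (k, rows, cols)")
        if arr.shape[1:] != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("surface shape does not match grid spec")
        if len(self.labels) != arr.shape[0]:
            raise ValueError("one label per surface required")
        object.__setattr__(self, "surfaces", arr)

    @property
    def k(self) -> int:
        return self.surfaces.shape[0]

    def valid_mask(self) -> np.ndarray:
        return np.all(self.surfaces != self.nodata, axis=0)


def pixel_sd(ensemble: SurfaceEnsemble) -> np.ndarray:
    """Cellwise sample standard deviation (denominator k - 1) across models."""
    valid = ensemble.valid_mask()
    sd = np.std(ensemble.surfaces, axis=0, ddof=1)
    return np.where(valid, sd, ensemble.nodata)


def _region_stats(
    surface: np.ndarray, mask: RegionMask, region_id: int, nodata: float
) -> tuple[np.ndarray, float, float]:
    region = mask.cells(region_id) & (surface != nodata)
    n = int(np.sum(region))
    if n < 2:
        raise ValueError(f"region {region_id} has {n} valid cells; need >= 2")
    vals = surface[region]
    return region, float(np.mean(vals)), float(np.std(vals, ddof=1))


def significance_2sd(
    shift_surface: np.ndarray,
    mask: RegionMask,
    region_id: int,
    nodata: float = NODATA,
) -> np.ndarray:
    """Flag cells whose value departs from the region mean by more than 2 SD.

    Under a normal model such departures are significant at ~95%.
    Returns a boolean surface; cells outside the region are False.
    """
    region, mu, sd = _region_stats(shift_surface, mask, region_id, nodata)
    out = np.zeros_like(region, dtype=bool)
    out[region] = np.abs(shift_surface[region] - mu) > 2.0 * sd
    return out


def zscore_map(
    shift_surface: np.ndarray,
    mask: RegionMask,
    region_id: int,
    nodata: float = NODATA,
) -> np.ndarray:
    """Standardise a region's values: (x - mu) / sd over the region's cells.

    Cells outside the region (or nodata) carry the nodata sentinel.  A
    zero-SD region raises rather than returning silent zeros.
    """
    region, mu, sd = _region_stats(shift_surface, mask, region_id, nodata)
    if sd == 0.0:
        raise ValueError(f"region {region_id} has zero SD; z-scores undefined")
    out = np.full(shift_surface.shape, nodata)
    out[region] = (shift_surface[region] - mu) / sd
    return out


def harmonic_mean_surface(ensemble: SurfaceEnsemble) -> np.ndarray:
    """Cellwise harmonic mean of exactly three model surfaces.

    3 / (1/x1 + 1/x2 + 1/x3); any nonpositive input makes the cell 0 (the
    harmonic mean is undefined there, and 0 is the conservative "no
    agreement on suitability" value).
    """
    if ensemble.k != 3:
        raise ValueError(f"harmonic mean defined for 3 surfaces, got {ensemble.k}")
    valid = ensemble.valid_mask()
    x = ensemble.surfaces
    any_nonpos = np.any(x <= 0.0, axis=0)
    n_zeroed = int(np.sum(any_nonpos & valid))
    if n_zeroed:
        logger.warning(
            "harmonic_mean_surface: %d cells with nonpositive input set to 0", n_zeroed
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = 3.0 / np.sum(1.0 / x, axis=0)
    hm = np.where(any_nonpos, 0.0, hm)
    return np.where(valid, hm, ensemble.nodata)


@dataclass(frozen=True)
class MonteCarloResult:
    """Result of the R-factor resampling.

    rf = sd_n * (uq - lq): the sample SD of the observations times the
    95% inter-quantile width (97.5th minus 2.5th percentile) of ``n``
    normal resamples drawn from the observations' fitted mean and SD.
    """

    n: int
    uq: float
    lq: float
    sd_n: float
    rf: float
    seed: int
    mean: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.lq > self.uq:
            raise ValueError("lower quantile exceeds upper quantile")
        if self.rf < 0:
            raise ValueError("R-factor must be nonnegative")


def rfactor_mc(
    observed: np.ndarray | list[float],
    n: int = 100,
    ci: float = 95.0,
    seed: int = 0,
) -> MonteCarloResult:
    """Monte-Carlo prediction-uncertainty statistic for a set of values.

    Fits a normal distribution to the observed values (mean, sample SD),
    draws ``n`` points, takes the upper/lower quantiles of the draws at the
    requested confidence level (97.5%/2.5% for ci=95), and returns
    rf = sd_n * (uq - lq).  Quantiles use linear interpolation between order
    statistics.  Constant input gives rf = 0.
    """
    obs = np.asarray(observed, dtype=np.float64).ravel()
    if obs.size < 2:
        raise ValueError("need at least 2 observed values")
    if n < 2:
        raise ValueError("need at least 2 resamples")
    mu = float(np.mean(obs))
    sd_n = float(np.std(obs, ddof=1))
    rng = np.random.default_rng(seed)
    draws = rng.normal(mu, sd_n, size=n)
    alpha = (100.0 - ci) / 2.0
    lq = float(np.percentile(draws, alpha))
    uq = float(np.percentile(draws, 100.0 - alpha))
    rf = sd_n * (uq - lq)
    return MonteCarloResult(n=n, uq=uq, lq=lq, sd_n=sd_n, rf=rf, seed=seed, mean=mu)
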