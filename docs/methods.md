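# Methods

## The suitability model

`foragecast` scores the climatic suitability of a perennial forage grass
for one location from twelve monthly values each of mean-minimum
temperature, mean-maximum temperature and precipitation. The model is
mechanistic: a species is a set of cardinal thresholds, and the score is a
deterministic function of climate against those thresholds, with no
statistical fitting.

For each of the 12 candidate growing seasons (start months wrap December
to January; an optional `g_min`/`g_max` calendar window restricts them):

- **Kill rule.** If any season month's mean minimum temperature is
  strictly below the kill temperature `ktmp`, the season scores 0. The
  comparison uses the monthly mean-minimum layer directly; classic
  DIVA-GIS builds subtract a hardiness buffer from monthly tmin first, so
  an optional `ktmp_offset` (default 0 °C) reproduces that behaviour.
- **Temperature.** Each season month gets a trapezoidal membership of its
  temperature against `(t_min, t_opmin, t_opmax, t_max)` — 0 outside the
  support, 100 on the optimal plateau, linear shoulders. The season's
  temperature score is the *minimum* over its months (a growing season is
  only as good as its worst month; this is the standard, most conservative
  reading). It is computed twice, once on the tmin series and once on the
  tmax series, because warm-season grasses can be limited by cool nights
  and hot days independently.
- **Rainfall.** One trapezoid of the season's *total* precipitation
  against `(r_min, r_opmin, r_opmax, r_max)`.
- **Combination.** Per season, temperature × rainfall / 100 (a
  `season_combiner="min"` switch takes the minimum of the two instead);
  the tmin-driven and tmax-driven results merge through the piecewise
  ratio-of-squares rule (the nonzero branch when one side is zero; both
  zero gives 0, a case the piecewise definition leaves open). The cell
  keeps the best season.

Scores are percentages. Class labels follow the conventional bins:
0 unsuitable, (0,20] very marginal, (20,40] marginal, (40,60] suitable,
(60,80] very suitable, (80,100] excellent; ≥ 40 counts as "adequately
suitable" in area statistics (inclusive, configurable).

The gridded engine (`raster.suitability_surface`) loops over seasons and
months in exactly the same order as the per-cell evaluator and uses
explicit multiplication rather than `**2`, so vectorised and scalar paths
agree *bit for bit*; the test suite asserts exact equality against an
independently written brute-force evaluator on thousands of random cells.

## Geometry and area statistics

Grids are regular lon/lat (WGS84), cell-centre registered, row 0 north,
default 5 arc-min cells. A cell's area is the spherical-zone slice
(π/180)·R²·Δλ·|sin φ_top − sin φ_bottom| with R = 6371 km, so "percent of
a region suitable" is a true area fraction, not a cell count. Nodata
cells (sentinel −9999) are excluded from both numerator and denominator.
Suitability shifts are current minus future percentages: positive = loss.

Rasters are stored as ESRI ASCII grids — a six-line header plus
whitespace-separated values — written with `repr` precision so write→read
round-trips are bit-exact. One text format keeps every artifact diffable
and checksummable.

## Uncertainty statistics

- Pixelwise spread across k model surfaces uses the sample SD (k − 1).
- Region significance: |x − mean| > 2·SD of the region's cells (≈95%
  under a normal model).
- z-scores standardise a region's values; a zero-SD region raises rather
  than silently returning zeros.
- The harmonic mean of three model surfaces, 3/(1/x₁+1/x₂+1/x₃), is 0
  whenever any input is ≤ 0 (logged): the harmonic mean is undefined
  there and 0 is the conservative "no agreement" value.
- The Monte-Carlo R-factor fits a normal distribution to the observed
  values (mean, sample SD), draws n = 100 points from a seeded generator,
  and returns Rf = SD_N·(Uq − Lq) with Uq/Lq the 97.5th/2.5th percentiles
  of the draws (linear interpolation between order statistics). Constant
  input gives Rf = 0; the statistic scales linearly in the observations'
  SD.

## Feed-balance arithmetic

Per-head demand is live weight × 2.5%/day × 365 days: 1.825 t DM/yr for a
200 kg local animal, 5.475 t for a 600 kg exotic one. Regional demand is
head count × mix-weighted per-head demand, rounded half away from zero to
whole tons *at region level*; totals are sums of the rounded regions
(this reproduces published regional feed tables exactly). The printed
grand total of head counts in the source census table is internally
inconsistent with its own column; the package always sums the regional
counts (53,430,458).

Supply: pasture area = region area × pasture fraction (0.15 now, 0.10
projected) × suitable fraction. Management regimes fix yields — 5.7 t
DM/ha/yr for every grass under business-as-usual, species-best 16
(Buffel), 30 (Napier), 18 (Rhodes) under good fertilisation. In the
allocation model each cell where at least one species meets the
suitability threshold goes to the species with the largest
score × yield *among those meeting the threshold* (a cell suitable only
for Buffel is never planted to a sub-threshold higher-yielding species;
ties break by raw score, then the fixed order Buffel, Napier, Rhodes);
remaining cells grow "other grasses" at 5.7 t/ha. Contribution % =
100 × supply/demand; the ±28% band reported alongside reflects the
spread of published min/mean/max yields and is carried as metadata, not
rederived. Regions are treated in isolation — no inter-regional trade.

## The synthetic world

The generator emulates the *structure* the analysis assumes, not any real
geography:

- **Grid.** 48 × 60 cells of 5 arc-min by default (tests use smaller
  grids); four equal latitude bands form pseudo-regions named after the
  study regions, north to south.
- **Temperature.** An elevation-like smooth field (sum of six seeded
  random-phase sinusoids) spans 16 °C — about 2500 m of relief at a
  6.5 °C/km lapse rate — below a 27 °C warm-lowland baseline, with a
  2 °C seasonal cycle peaking before the rains and a 12 °C diurnal range
  splitting tmin/tmax.
- **Rainfall.** One wet season: monthly shares follow a Gaussian in month
  number centred mid-July–August whose width grows with the annual total
  (wetter climates have longer rains), which keeps peak months below the
  350 mm cap observed in the wettest parts of the study area. Regional
  annual totals span 450–980 (Tigray-like), 850–1485 (Amhara-like),
  410–2000 (Oromia-like) and 500–2200 mm (SNNP-like), increasing west to
  east with mild seeded noise.
- **Futures.** Uniform warming of +1.96, +2.36 or +2.93 °C (the three
  GCM-derived 2050 offsets), optional zero-mean spatially correlated
  noise (default amplitude 0, so the area-mean warming is exact), and
  monthly precipitation deltas defaulting to −30 mm in July–August for
  the two single-model scenarios and +10 mm for the ensemble mean.
- **Crops.** Cardinal temperatures follow published ranges (Buffel
  optimum 30–35 °C; Napier growth 21–40 °C; Rhodes growth 20–37 °C);
  seasonal rainfall thresholds are published *annual* ranges scaled by
  g_used/12. Kill temperatures (2, 6, 2 °C) reflect the species' relative
  frost sensitivity.
- **Planted fixtures.** For end-to-end checks, a stack can be constructed
  so that a chosen fraction of a region's *area* is exactly optimal and
  the rest sits below t_min with zero rain; the achieved fraction (within
  one cell's area share of the target) is ground truth for recovery
  tests.

What passing tests on this world do show: the engine, the zonal
statistics, the uncertainty statistics and the scenario arithmetic are
internally correct and deterministic. What they do not show: fidelity to
real topography, real GCM anomaly patterns, bimodal rainfall regimes, or
the published real-data area percentages — those require the original
climate archives and are explicitly out of scope.

## Numerical choices and edge cases

- All scores clamp to [0, 100]; area fractions guard against float
  round-off past 100%.
- Rounding to whole tons/percent uses half-away-from-zero (matching the
  published tables), not banker's rounding.
- Growing periods given in days convert to whole months by round(d/30),
  minimum 1.
- Negative post-delta precipitation clips to 0 with a logged count.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the config; identical config + seed ⇒ identical run
  manifests (SHA-256 over every artifact).

## Problem sizes

Default synthetic runs use a 48 × 60 grid (2,880 cells × 36 monthly
layers); the acceptance script uses 32 × 40 and 1,000 random cells for
the oracle cross-check. These sizes give area fractions resolved to ~0.3%
of a region while keeping a full pipeline run under a second; the engine
is vectorised and scales linearly in cells, so 5 arc-min national grids
(~10⁵ cells) remain practical.

## Known limitations

- No soil, pest, disease, CO₂-fertilisation or waterlogging effects: the
  model is climate-only by design.
- The monthly-mean formulation cannot represent sub-monthly extremes; a
  single cold night kills in reality at finer granularity than a monthly
  mean minimum captures.
- The feed model balances dry matter only — not crude protein or
  metabolisable energy — and assumes monocrop pasture with no
  inter-regional trade.
- The "min" season-combiner variant and the ktmp buffer are provided for
  comparability with other ECOCROP lineages but are not the defaults.
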