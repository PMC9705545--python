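"""End-to-end orchestration: climate -> suitability -> areas -> feed balance.

A run is driven by a :class:`RunConfig` (constructable from a YAML file).
Inputs are either synthetic (generated on the fly from a seed) or paths to
climate-stack directories, a region-mask raster, a crop CSV and a herd CSV.
Every stage writes plain-text artifacts into the output directory and the
run closes with a manifest of SHA-256 checksums, so identical configs and
seeds yield identical manifests.

Outputs
-------
``suitability/<species>_<climate>.asc``   per-species suitability rasters
``areas.csv``        suitable-area % per region x species x climate
``shifts.csv``       current minus future suitable-area % (positive = loss)
``uncertainty/``     cross-scenario SD and harmonic-mean rasters
``rfactor.csv``      Monte-Carlo R-factor per region x species
``demand.csv``       herd DM demand per region x herd scenario
``contributions.csv``  per-species monocrop contribution % (Table-2 style)
``allocation.csv``   best suitability x productivity allocation (Fig-3 style)
``manifest.json``    config hash, versions, seeds, per-file checksums
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecocrop import CropParameters, read_crop_csv
from .feed import (
    HerdScenario,
    LandScenario,
    ManagementScenario,
    RegionHerd,
    SCENARIO_A,
    SCENARIO_B,
    MGMT_LOW_YIELD,
    MGMT_HIGH_YIELD,
    allocate_best,
    feed_balance,
    herd_demand,
    pasture_area_ha,
    read_herd_csv,
    species_contribution,
    KM2_TO_HA,
)
from .raster import (
    ClimateStack,
    RegionMask,
    SuitabilitySurface,
    cell_area_grid,
    read_ascii_grid,
    suitability_surface,
    suitable_area_fraction,
    suitability_shift,
)
from .synthetic import (
    SyntheticConfig,
    default_crop_parameters,
    default_herd_table,
    generate_current,
    generate_future,
)
from .uncertainty import SurfaceEnsemble, pixel_sd, harmonic_mean_surface, rfactor_mc

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report_tables"]

logger = logging.getLogger(__name__)

_HALF = 0.5


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + _HALF)) if x >= 0 else -int(math.floor(-x + _HALF))


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; every default is overridable."""

    out_dir: str = "foragecast_run"
    seed: int = 0
    threshold: float = 40.0
    land_fractions: tuple[float, ...] = (0.15, 0.10)
    herd_scenarios: tuple[HerdScenario, ...] = (SCENARIO_A, SCENARIO_B)
    managements: tuple[ManagementScenario, ...] = (MGMT_LOW_YIELD, MGMT_HIGH_YIELD)
    # synthetic-input knobs (used when no climate paths are given)
    synthetic: SyntheticConfig | None = None
    # optional real inputs
    current_stack_dir: str | None = None
    future_stack_dirs: Mapping[str, str] = field(default_factory=dict)
    region_mask_path: str | None = None
    crop_csv: str | None = None
    herd_csv: str | None = None
    rfactor_n: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in (
            "out_dir",
            "seed",
            "threshold",
            "current_stack_dir",
            "region_mask_path",
            "crop_csv",
            "herd_csv",
            "rfactor_n",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "land_fractions" in raw:
            kwargs["land_fractions"] = tuple(float(v) for v in raw["land_fractions"])
        if "future_stack_dirs" in raw:
            kwargs["future_stack_dirs"] = dict(raw["future_stack_dirs"])
        if "herd_scenarios" in raw:
            kwargs["herd_scenarios"] = tuple(
                HerdScenario(s["label"], float(s["f_local"]), float(s["f_exotic"]))
                for s in raw["herd_scenarios"]
            )
        if "managements" in raw:
            kwargs["managements"] = tuple(
                ManagementScenario(m["label"], dict(m["yields_t_per_ha"]))
                for m in raw["managements"]
            )
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig(**raw["synthetic"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    version: str
    seed: int
    checksums: dict[str, str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(
    cfg: RunConfig,
) -> tuple[dict[str, ClimateStack], RegionMask, list[CropParameters], pd.DataFrame]:
    """Resolve climate stacks, mask, crops and herd from config or synthesis."""
    if cfg.current_stack_dir is not None:
        current = ClimateStack.from_dir(cfg.current_stack_dir)
        if cfg.region_mask_path is None:
            raise ValueError("region_mask_path required with explicit climate inputs")
        ids, spec = read_ascii_grid(cfg.region_mask_path)
        names = {int(i): f"region_{int(i)}" for i in np.unique(ids) if i > 0}
        mask = RegionMask(spec=spec, ids=ids.astype(np.int32), names=names)
        climates = {"current": current}
        for label, d in cfg.future_stack_dirs.items():
            climates[label] = ClimateStack.from_dir(d)
    else:
        syn = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
        current, mask = generate_current(syn)
        climates = {"current": current}
        for label in syn.warming_offsets:
            climates[label] = generate_future(current, label, syn)
    crops = (
        read_crop_csv(cfg.crop_csv) if cfg.crop_csv else default_crop_parameters()
    )
    herd = read_herd_csv(cfg.herd_csv) if cfg.herd_csv else default_herd_table()
    return climates, mask, crops, herd


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    climates, mask, crops, herd = _load_inputs(cfg)
    region_ids = mask.region_ids()
    future_labels = [c for c in climates if c != "current"]

    # --- suitability surfaces -------------------------------------------
    suit_dir = out / "suitability"
    suit_dir.mkdir(exist_ok=True)
    surfaces: dict[tuple[str, str], SuitabilitySurface] = {}
    for p in crops:
        for label, stack in climates.items():
            logger.info("suitability: %s under %s", p.species_name, label)
            surf = suitability_surface(stack, p, climate_label=label)
            surfaces[(p.species_name, label)] = surf
            surf.write(suit_dir / f"{p.species_name}_{label}.asc")

    # --- area statistics and shifts -------------------------------------
    area_rows = []
    for (species, label), surf in surfaces.items():
        for rid in region_ids:
            pct = suitable_area_fraction(surf, mask, rid, cfg.threshold)
            area_rows.append(
                {
                    "region": mask.names[rid],
                    "species": species,
                    "climate": label,
                    "suitable_pct": pct,
                }
            )
    areas = pd.DataFrame(area_rows)
    shift_rows = []
    cur = areas[areas.climate == "current"].set_index(["region", "species"])
    for label in future_labels:
        fut = areas[areas.climate == label].set_index(["region", "species"])
        for idx in cur.index:
            shift_rows.append(
                {
                    "region": idx[0],
                    "species": idx[1],
                    "climate": label,
                    "shift_pct": suitability_shift(
                        float(cur.loc[idx, "suitable_pct"]),
                        float(fut.loc[idx, "suitable_pct"]),
                    ),
                }
            )
    shifts = pd.DataFrame(shift_rows)

    # --- cross-scenario uncertainty --------------------------------------
    unc_dir = out / "uncertainty"
    unc_dir.mkdir(exist_ok=True)
    rf_rows = []
    if len(future_labels) >= 2:
        for p in crops:
            stack_arr = np.stack(
                [surfaces[(p.species_name, l)].scores for l in future_labels]
            )
            ens = SurfaceEnsemble(
                spec=mask.spec, surfaces=stack_arr, labels=tuple(future_labels)
            )
            sd = pixel_sd(ens)
            _write_layer(sd, mask, unc_dir / f"{p.species_name}_sd.asc")
            if len(future_labels) == 3:
                hm = harmonic_mean_surface(ens)
                _write_layer(hm, mask, unc_dir / f"{p.species_name}_hmean.asc")
            for rid in region_ids:
                vals = [
                    float(
                        suitable_area_fraction(
                            surfaces[(p.species_name, l)], mask, rid, cfg.threshold
                        )
                    )
                    for l in future_labels
                ]
                mc = rfactor_mc(vals, n=cfg.rfactor_n, seed=cfg.seed)
                rf_rows.append(
                    {
                        "region": mask.names[rid],
                        "species": p.species_name,
                        "rf": mc.rf,
                        "sd_n": mc.sd_n,
                        "uq": mc.uq,
                        "lq": mc.lq,
                        "n": mc.n,
                    }
                )
    rfactors = pd.DataFrame(rf_rows)

    # --- feed demand ------------------------------------------------------
    demand_rows = []
    for _, row in herd.iterrows():
        rh = RegionHerd(str(row["region"]), int(row["n_cattle"]))
        for hs in cfg.herd_scenarios:
            demand_rows.append(
                {
                    "region": rh.region,
                    "herd_scenario": hs.label,
                    "n_cattle": rh.n_cattle,
                    "demand_t": herd_demand(rh, hs),
                }
            )
    demand = pd.DataFrame(demand_rows)
    totals = (
        demand.groupby("herd_scenario", as_index=False)
        .agg(demand_t=("demand_t", "sum"), n_cattle=("n_cattle", "sum"))
        .assign(region="Total")
    )
    demand = pd.concat([demand, totals[demand.columns]], ignore_index=True)

    # --- contributions (per-species monocrop) and allocation -------------
    region_area_ha = {
        rid: float(np.sum(cell_area_grid(mask.spec)[mask.cells(rid)])) * KM2_TO_HA
        for rid in region_ids
    }
    herd_by_region = {str(r["region"]): int(r["n_cattle"]) for _, r in herd.iterrows()}
    contrib_rows = []
    alloc_rows = []
    for label in ["current", *future_labels]:
        for land_f in cfg.land_fractions:
            land = LandScenario(land_f)
            for hs in cfg.herd_scenarios:
                for rid in region_ids:
                    rname = mask.names[rid]
                    if rname not in herd_by_region:
                        continue
                    dem = herd_demand(RegionHerd(rname, herd_by_region[rname]), hs)
                    for mgmt in cfg.managements:
                        for p in crops:
                            pct = suitable_area_fraction(
                                surfaces[(p.species_name, label)],
                                mask,
                                rid,
                                cfg.threshold,
                            )
                            area = pasture_area_ha(region_area_ha[rid], land, pct)
                            contrib_rows.append(
                                {
                                    "climate": label,
                                    "land_fraction": land_f,
                                    "herd_scenario": hs.label,
                                    "management": mgmt.label,
                                    "region": rname,
                                    "species": p.species_name,
                                    "contribution_pct": _round_half_away(
                                        species_contribution(
                                            area,
                                            mgmt.yields_t_per_ha[p.species_name],
                                            dem,
                                        )
                                    ),
                                }
                            )
                    # allocation uses the high-yield regime (best productivity)
                    mgmt = cfg.managements[-1]
                    alloc = allocate_best(
                        {
                            p.species_name: surfaces[(p.species_name, label)]
                            for p in crops
                        },
                        mask,
                        rid,
                        land,
                        mgmt,
                        cfg.threshold,
                    )
                    rep = feed_balance(alloc, mgmt, dem)
                    row = {
                        "climate": label,
                        "land_fraction": land_f,
                        "herd_scenario": hs.label,
                        "region": rname,
                        "demand_t": dem,
                    }
                    for s in alloc.areas_ha:
                        row[f"{s}_pct"] = _round_half_away(rep.contribution_pct[s])
                    row["other_grass_pct"] = _round_half_away(rep.other_grass_pct)
                    row["total_pct"] = _round_half_away(rep.total_contribution_pct)
                    alloc_rows.append(row)
    contributions = pd.DataFrame(contrib_rows)
    allocation = pd.DataFrame(alloc_rows)

    tables = {
        "areas.csv": areas,
        "shifts.csv": shifts,
        "rfactor.csv": rfactors,
        "demand.csv": demand,
        "contributions.csv": contributions,
        "allocation.csv": allocation,
    }
    report_tables(tables, out)

    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        version=__version__,
        seed=cfg.seed,
        checksums={f: _sha256(out / f) for f in files},
    )
    manifest.write(out / "manifest.json")
    return manifest


def _write_layer(arr: np.ndarray, mask: RegionMask, path: Path) -> None:
    from .raster import write_ascii_grid

    write_ascii_grid(arr, mask.spec, path)


def report_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> None:
    """Write result tables as CSV with stable column order and row order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
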