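"""End-to-end pipeline driver: simulate, build, validate.

``build_from_bundle`` runs the six method stages in memory and is the
core entry point; ``run_simulate`` / ``run_build`` / ``run_validate``
wrap it with directory I/O and structured logging for the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allocate, harmonize, regional, validate
from .allocate import CropGridStack
from .grid import Grid
from .io import load_bundle, output_name, read_grid, save_bundle, write_grid
from .synthetic import WorldConfig, make_survey_points, make_world

__all__ = ["PipelineConfig", "BuildResult", "build_from_bundle",
           "run_simulate", "run_build", "run_validate"]

log = logging.getLogger("irrigrid")


@dataclass
class PipelineConfig:
    """Configuration shared by the simulate/build/validate commands."""

    input_dir: str = "world"
    output_dir: str = "build"
    ratio_orientation: str = "inverted"
    cap_ha: float | None = None          # default: the cell area
    min_ip_pct: float = 0.3
    block_km: float = 4.0
    include_potential: bool = False
    float32: bool = False
    seed: int = 0
    n_survey_points: int = 200
    world: dict = field(default_factory=dict)   # WorldConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class BuildResult:
    """In-memory result of a full build: per-year stacks plus diagnostics."""

    taei_1km: Grid
    growing: dict[int, CropGridStack]
    aai_uncapped: dict[int, CropGridStack]
    aai_capped: dict[int, CropGridStack]
    aai_final: dict[int, CropGridStack]
    rainfed: dict[int, CropGridStack]
    uaa: Grid
    targets: pd.DataFrame
    calibration: pd.DataFrame
    diagnostics: pd.DataFrame


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def build_from_bundle(bundle, ratio_orientation: str = "inverted",
                      cap_ha: float | None = None) -> BuildResult:
    """Run the full disaggregation method on a world bundle.

    Stages: (i) hierarchy disaggregation of annual totals, (ii) crop-wise
    disaggregation, (iii) equipped-area harmonization to the target grid,
    (iv) crop growing areas, (v) crop equipped areas and zonal sums,
    (vi) calibration, allocation, capacity cap and rainfed derivation.
    """
    cfg = bundle.config
    regions = bundle.region_table
    rr = bundle.region_raster

    # (i) annual totals down to NUTS2
    shares = regional.compute_region_shares(bundle.crop_aai_ref, regions)
    nuts2_series = regional.disaggregate_total_aai(bundle.aai_series, shares,
                                                   regions)
    # (ii) crop-wise targets
    crop_props = regional.compute_crop_proportions(bundle.crop_aai_ref)
    targets = regional.crop_aai_series(nuts2_series, crop_props)
    unallocated = regional.unallocated_totals(nuts2_series, crop_props)
    for rec in unallocated.itertuples(index=False):
        log.info("stage=crop_split region=%s year=%s unallocated_ha=%.3f",
                 rec.region_id, rec.year, rec.unallocated_ha)

    # (iii) harmonize equipped area onto the 1-km target grid
    coarse_2005, n_nodata = harmonize.aggregate_block_sum(
        bundle.aei_fine_2005, cfg.coarse_factor)
    if n_nodata:
        log.info("stage=block_sum nodata_cells=%d", n_nodata)
    ratio, flagged = harmonize.change_ratio(coarse_2005, bundle.aei_coarse_2010,
                                            ratio_orientation)
    if flagged.any():
        log.info("stage=change_ratio zero_denominator_cells=%d",
                 int(flagged.sum()))
    taei_1km = harmonize.harmonized_aei(
        harmonize.resample_bilinear(bundle.aei_fine_2005,
                                    bundle.target_geometry),
        harmonize.resample_bilinear(ratio, bundle.target_geometry))

    growing, aai_unc, aai_cap, aai_fin, rainfed = {}, {}, {}, {}, {}
    calib_all, diag_rows = [], []
    uaa = allocate.uaa_grid(bundle.weight_grid)
    for year in cfg.year_list:
        share_grids = bundle.crop_share_grids[year]
        # (iv) crop growing area
        ga = allocate.crop_growing_area(bundle.weight_grid, share_grids)
        # (v) crop equipped area and zonal sums
        aei = allocate.crop_aei(share_grids, taei_1km)
        regional_aei = allocate.zonal_sum(aei, rr)
        # (vi) calibrate, allocate, cap, clamp
        calib = allocate.calibration(targets[targets["year"] == year],
                                     regional_aei)
        stack = allocate.allocate_aai(aei, calib, rr, year)
        capped, cap_diag = allocate.apply_cell_cap(stack, cap_ha, rr)
        rf, final, clamp_diag = allocate.derive_rainfed(ga, capped)

        growing[year], aai_unc[year], aai_cap[year] = ga, stack, capped
        aai_fin[year], rainfed[year] = final, rf
        calib_all.append(calib)
        for rec in calib[calib["flagged"]].itertuples(index=False):
            log.info("stage=calibration region=%s crop=%s year=%s "
                     "unallocated_ha=%.3f", rec.region_id, rec.crop_code,
                     year, rec.regional_target_ha)
        flagged_tbl = (calib[calib["flagged"]]
                       .groupby("region_id")["regional_target_ha"].sum())
        cap_tbl = cap_diag.set_index("region_id")["clipped_ha"]
        clamp_tbl = clamp_diag.set_index("crop_code")["clamped_ha"]
        for rid in rr.region_ids:
            diag_rows.append({
                "region_id": rid, "crop_code": "", "year": year,
                "unallocated_ha": float(flagged_tbl.get(rid, 0.0)),
                "cap_clipped_ha": float(cap_tbl.get(rid, 0.0)),
                "clamp_clipped_ha": 0.0,
            })
        for code in final.crop_codes:
            diag_rows.append({
                "region_id": "<all>", "crop_code": code, "year": year,
                "unallocated_ha": 0.0, "cap_clipped_ha": 0.0,
                "clamp_clipped_ha": float(clamp_tbl.get(code, 0.0)),
            })

    return BuildResult(
        taei_1km=taei_1km, growing=growing, aai_uncapped=aai_unc,
        aai_capped=aai_cap, aai_final=aai_fin, rainfed=rainfed, uaa=uaa,
        targets=targets, calibration=pd.concat(calib_all, ignore_index=True),
        diagnostics=pd.DataFrame(diag_rows),
    )


def write_build(result: BuildResult, out_dir: str | Path,
                region_mask: np.ndarray | None = None,
                float32: bool = False) -> Path:
    """Write all product rasters and diagnostics for a build result."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodata = -9999.0

    def masked(arr: np.ndarray) -> Grid:
        v = arr if region_mask is None else np.where(region_mask, arr, nodata)
        return Grid(v, result.taei_1km.geometry, nodata, "ha")

    for year, final in result.aai_final.items():
        rf = result.rainfed[year]
        ga = result.growing[year]
        for code in final.crop_codes:
            write_grid(masked(final[code]), out / output_name(code, "IR", year),
                       float32)
            write_grid(masked(rf[code]), out / output_name(code, "RF", year),
                       float32)
            write_grid(masked(ga[code]), out / output_name(code, "A", year),
                       float32)
        write_grid(masked(np.asarray(final.total())),
                   out / output_name("Total", "IR", year), float32)
        write_grid(masked(np.asarray(rf.total())),
                   out / output_name("Total", "RF", year), float32)
        # the product UAA layer is the crop-covered agricultural area, so the
        # identity UAA = Total_IR + Total_RF holds exactly
        write_grid(masked(np.asarray(ga.total())),
                   out / output_name("", "UAA", year), float32)
    result.calibration.to_csv(out / "calibration.csv", index=False)
    result.diagnostics.to_csv(out / "diagnostics.csv", index=False)
    result.targets.to_csv(out / "targets.csv", index=False)
    return out


@_stage("simulate")
def run_simulate(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Generate a synthetic world and survey points under ``out_dir``."""
    out = Path(out_dir if out_dir is not None else config.input_dir)
    wc = WorldConfig(seed=config.seed, **config.world)
    bundle = make_world(wc)
    save_bundle(bundle, out)
    for year in wc.year_list:
        pts = make_survey_points(bundle, config.n_survey_points, year,
                                 seed=config.seed + year)
        pts.to_csv(out / f"survey_points_{year}.csv", index=False)
    log.info("stage=simulate seed=%d out=%s", config.seed, out)
    return out


@_stage("build")
def run_build(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Load a world directory, run the method, write the product rasters."""
    bundle = load_bundle(config.input_dir)
    result = build_from_bundle(bundle, config.ratio_orientation, config.cap_ha)
    out = Path(out_dir if out_dir is not None else config.output_dir)
    write_build(result, out, bundle.region_raster.mask(), config.float32)
    log.info("stage=build in=%s out=%s", config.input_dir, out)
    return out


@_stage("validate")
def run_validate(config: PipelineConfig, build_dir: str | Path | None = None,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Compare survey points against built rasters; write per-crop stats."""
    world = Path(config.input_dir)
    build = Path(build_dir if build_dir is not None else config.output_dir)
    out = Path(out_dir if out_dir is not None else build)
    out.mkdir(parents=True, exist_ok=True)

    cfg_raw = yaml.safe_load((world / "config.yaml").read_text())
    years = list(range(cfg_raw["years"][0], cfg_raw["years"][1] + 1))
    crop_codes = list(WorldConfig(**{**cfg_raw, "years": tuple(cfg_raw["years"])}
                                  ).crop_codes)

    point_tables, raster_tables = [], []
    for year in years:
        pts_path = world / f"survey_points_{year}.csv"
        if not pts_path.exists():
            continue
        pts = pd.read_csv(pts_path, keep_default_na=False)
        pts = validate.classify_survey_points(pts, config.include_potential)
        geom = None
        layers = {}
        for code in crop_codes:
            grid = read_grid(build / output_name(code, "IR", year))
            geom = grid.geometry
            layers[code] = grid.values
        stack = CropGridStack(layers, geom, "aai", year)
        # pool years after per-year block aggregation
        pt = validate.block_irrigated_percentage_points(pts, geom,
                                                        config.block_km)
        rt = validate.block_irrigated_percentage_raster(stack, config.block_km)
        pt["year"] = year
        rt["year"] = year
        point_tables.append(pt)
        raster_tables.append(rt)
    if not point_tables:
        raise ValueError(f"no survey point files found under {world}")
    paired = validate.paired_filter(pd.concat(point_tables, ignore_index=True),
                                    pd.concat(raster_tables, ignore_index=True),
                                    config.min_ip_pct)
    stats = validate.agreement_stats(paired)
    stats.to_csv(out / "validation_stats.csv", index=False)
    log.info("stage=validate blocks=%d crops=%d", len(paired), len(stats))
    return stats
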