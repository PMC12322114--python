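"""Seeded synthetic input worlds with exact per-cell ground truth.

The generator inverts the generative assumptions of the allocation
method so that the full pipeline can recover a known truth exactly:

* regions are contiguous rectangular tiles (a NUTS1 band split into
  NUTS2 strips), carried as a membership raster;
* the within-region irrigation fraction of each crop factors as
  ``p[region, crop, year] = q[region, crop] * m[nuts1, year]`` — crop
  composition and the NUTS2-within-NUTS1 split are therefore constant in
  time, which is exactly the constancy the disaggregation assumes;
* crop growing shares are drawn once per cell (symmetric Dirichlet with
  a slack component, so the crop sum stays below 1) and held constant
  across years;
* the coarse 2010 equipped-area raster is defined as a change ratio
  times the block sum of the fine 2005 raster; with ``ratio_mode
  "constant"`` the ratio field is spatially flat, so its bilinear
  resampling is exact and coarse-scale mass is conserved.

Ground truth per cell is ``p`` times the crop-specific equipped area
computed through the same harmonization formulas the pipeline applies;
the regional annual series and the reference-year crop table are then
*derived from the truth* by aggregation, so the pipeline's targets are
self-consistent by construction.

Randomness is split into independent child streams (regions, equipped
area, shares, fractions) of one seed, and survey-point sampling takes
its own seed, so drawing more points never perturbs the world.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .allocate import CropGridStack, crop_growing_area
from .crops import CROP_CODES
from .grid import Grid, GridGeometry, RegionRaster
from .harmonize import (aggregate_block_sum, change_ratio, harmonized_aei,
                        resample_bilinear)

__all__ = ["WorldConfig", "WorldBundle", "make_world", "make_survey_points"]

NODATA = -9999.0


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a synthetic study region.

    The fine equipped-area grid doubles as the 1-km target grid by
    default (identity resampling); ``target_offset_cells`` shifts the
    target lattice by that fraction of a cell to exercise true bilinear
    weights.  ``cap_trigger`` rescales one designated cell's equipped
    area so its unconstrained crop-summed allocation exceeds the
    per-cell capacity, for capacity-cap tests.
    """

    grid_height: int = 32
    grid_width: int = 32
    cell_size: float = 1000.0          # metres
    coarse_factor: int = 8
    n_nuts1: int = 3
    nuts2_per_nuts1: int = 2
    n_crops: int = 16
    years: tuple[int, int] = (2010, 2020)
    ratio_mode: str = "constant"
    constant_ratio: float = 0.9
    seed: int = 0
    n_nuts1_reported: int = 1          # NUTS1 units whose series stays at NUTS1
    target_offset_cells: float = 0.0
    cap_trigger: bool = False

    def __post_init__(self) -> None:
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.grid_height % self.coarse_factor or self.grid_width % self.coarse_factor:
            raise ValueError(
                f"grid {self.grid_height}x{self.grid_width} not divisible by "
                f"coarse factor {self.coarse_factor}"
            )
        if self.n_nuts1 < 1 or self.nuts2_per_nuts1 < 1 or self.n_crops < 1:
            raise ValueError("all counts must be positive")
        if self.n_nuts1 > self.grid_height:
            raise ValueError("more NUTS1 bands than grid rows")
        if self.nuts2_per_nuts1 > self.grid_width:
            raise ValueError("more NUTS2 strips than grid columns")
        if self.years[0] > self.years[1]:
            raise ValueError("year range must be non-decreasing")
        if not 0 <= self.n_nuts1_reported <= self.n_nuts1:
            raise ValueError("n_nuts1_reported out of range")
        if self.ratio_mode not in ("constant", "smooth"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")
        if self.cap_trigger and self.target_offset_cells != 0.0:
            raise ValueError("cap_trigger requires an identity target grid")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def crop_codes(self) -> tuple[str, ...]:
        if self.n_crops <= len(CROP_CODES):
            return CROP_CODES[: self.n_crops]
        return CROP_CODES + tuple(
            f"CROP{k}" for k in range(len(CROP_CODES), self.n_crops)
        )


@dataclass
class WorldBundle:
    """All pipeline inputs plus the per-cell ground truth they encode."""

    config: WorldConfig
    region_table: pd.DataFrame
    region_raster: RegionRaster
    aai_series: pd.DataFrame            # region_id, year, taai_ha
    crop_aai_ref: pd.DataFrame          # region_id, crop_code, aai_ha (reference yr)
    aei_fine_2005: Grid
    aei_coarse_2010: Grid
    weight_grid: Grid                   # percent, may exceed 100 before capping
    crop_share_grids: dict[int, dict[str, Grid]]   # year -> crop -> fraction grid
    truth_aai: dict[int, CropGridStack]            # year -> per-crop hectares
    taei_1km_2010: Grid                 # harmonized equipped area on target grid
    target_geometry: GridGeometry
    reference_year: int = 2010

    def truth_regional(self) -> pd.DataFrame:
        """Aggregate truth to (region_id, crop_code, year, aai_ha)."""
        rows = []
        idx = self.region_raster.indices
        inside = self.region_raster.mask()
        nreg = len(self.region_raster.region_ids)
        for year, stack in self.truth_aai.items():
            for code, arr in stack.layers.items():
                sums = np.bincount(idx[inside], weights=arr[inside], minlength=nreg)
                rows.extend((rid, code, year, float(s))
                            for rid, s in zip(self.region_raster.region_ids, sums))
        return pd.DataFrame(rows, columns=["region_id", "crop_code", "year", "aai_ha"])


def _region_partition(cfg: WorldConfig) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Rectangular tiling: NUTS1 row bands, each split into NUTS2 column strips."""
    rows = []
    indices = np.empty((cfg.grid_height, cfg.grid_width), dtype=np.int64)
    region_ids: list[str] = []
    row_bands = np.array_split(np.arange(cfg.grid_height), cfg.n_nuts1)
    col_strips = np.array_split(np.arange(cfg.grid_width), cfg.nuts2_per_nuts1)
    for h, band in enumerate(row_bands):
        n1 = f"N{h + 1}"
        rows.append((n1, "", "NUTS1"))
        for k, strip in enumerate(col_strips):
            n2 = f"{n1}{chr(65 + k)}"
            rows.append((n2, n1, "NUTS2"))
            indices[np.ix_(band, strip)] = len(region_ids)
            region_ids.append(n2)
    table = pd.DataFrame(rows, columns=["region_id", "parent_id", "level"])
    return table, indices, region_ids


def make_world(config: WorldConfig) -> WorldBundle:
    """Generate a complete synthetic input bundle with known truth."""
    cfg = config
    geom = GridGeometry(0.0, cfg.grid_height * cfg.cell_size, cfg.cell_size,
                        cfg.grid_height, cfg.grid_width)
    off = cfg.target_offset_cells * cfg.cell_size
    target_geom = GridGeometry(geom.x0 + off, geom.y0 - off, cfg.cell_size,
                               cfg.grid_height, cfg.grid_width)

    ss = np.random.SeedSequence(cfg.seed)
    s_regions, s_aei, s_shares, s_frac = ss.spawn(4)
    rng_aei = np.random.default_rng(s_aei)
    rng_shares = np.random.default_rng(s_shares)
    rng_frac = np.random.default_rng(s_frac)

    region_table, indices, region_ids = _region_partition(cfg)
    region_raster = RegionRaster(indices, region_ids, target_geom)

    # cell weights (percent of cell that is agricultural; a few exceed 100
    # to exercise the capping rule) and growing shares on the target grid
    weight = rng_aei.uniform(60.0, 110.0, size=target_geom.shape)
    weight_grid = Grid(weight, target_geom, NODATA, "percent")
    uaa_fraction = np.minimum(weight, 100.0) / 100.0

    # fine 2005 equipped area, at most half of the agricultural area of the
    # cell so that irrigated area can never exceed the growing area
    fine = rng_aei.uniform(0.0, 0.5, size=geom.shape) * uaa_fraction \
        * geom.cell_area_ha()
    # growing shares: symmetric Dirichlet with one slack component => sum < 1
    alpha = np.full(cfg.n_crops + 1, 0.8)
    shares = rng_shares.dirichlet(alpha, size=geom.shape)[..., : cfg.n_crops]
    # irrigation fractions p = q[region, crop] * m[nuts1, year]
    nreg = len(region_ids)
    q = rng_frac.uniform(0.05, 0.95, size=(nreg, cfg.n_crops))
    m = rng_frac.uniform(0.5, 1.0, size=(cfg.n_nuts1, len(cfg.year_list)))

    bundle = _assemble(cfg, geom, target_geom, region_table, region_raster,
                       weight_grid, fine, shares, q, m)

    if cfg.cap_trigger:
        # rescale the centre cell's equipped area so its unconstrained
        # crop-summed allocation reaches 1.5x the per-cell capacity in the
        # reference year, then rebuild everything downstream of it
        cap = target_geom.cell_area_ha()
        ci, cj = cfg.grid_height // 2, cfg.grid_width // 2
        y0 = cfg.year_list[0]
        cell_sum = sum(stack[ci, cj] for stack in
                       bundle.truth_aai[y0].layers.values())
        if cell_sum <= 0:
            raise ValueError("designated cap-trigger cell carries no irrigated area")
        fine = fine.copy()
        fine[ci, cj] *= 1.5 * cap / cell_sum
        bundle = _assemble(cfg, geom, target_geom, region_table, region_raster,
                           weight_grid, fine, shares, q, m)
    return bundle


def _assemble(cfg, geom, target_geom, region_table, region_raster,
              weight_grid, fine, shares, q, m) -> WorldBundle:
    """Deterministic part of world construction (no random draws)."""
    fine_2005 = Grid(fine, geom, NODATA, "ha")
    coarse_2005, _ = aggregate_block_sum(fine_2005, cfg.coarse_factor)
    if cfg.ratio_mode == "constant":
        ratio_field = np.full(coarse_2005.shape, cfg.constant_ratio)
    else:
        # smooth spatial ratio field around the configured mean
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 97)))
        noise = ndimage.gaussian_filter(
            rng.uniform(-1.0, 1.0, size=coarse_2005.shape), sigma=1.0)
        ratio_field = np.clip(cfg.constant_ratio + 0.3 * noise, 0.1, 1.5)
    coarse_2010 = Grid(ratio_field * coarse_2005.values, coarse_2005.geometry,
                       NODATA, "ha")

    # harmonize exactly as the pipeline will (inverted orientation)
    ratio_grid, _ = change_ratio(coarse_2005, coarse_2010, "inverted")
    ratio_1km = resample_bilinear(ratio_grid, target_geom)
    fine_1km = resample_bilinear(fine_2005, target_geom)
    taei_1km = harmonized_aei(fine_1km, ratio_1km)

    crop_codes = cfg.crop_codes
    share_grids_one_year = {
        code: Grid(np.ascontiguousarray(shares[..., c]), target_geom, NODATA,
                   "fraction")
        for c, code in enumerate(crop_codes)
    }
    crop_share_grids = {y: share_grids_one_year for y in cfg.year_list}

    idx = region_raster.indices
    truth_aai: dict[int, CropGridStack] = {}
    nuts1_of = region_table.set_index("region_id")["parent_id"]
    nuts1_ids = list(region_table.loc[region_table["level"] == "NUTS1",
                                      "region_id"])
    n1_index = np.array([nuts1_ids.index(nuts1_of[rid])
                         for rid in region_raster.region_ids])
    taei = taei_1km.values
    for yi, year in enumerate(cfg.year_list):
        layers = {}
        for c, code in enumerate(crop_codes):
            p_cell = q[idx, c] * m[n1_index[idx], yi]
            layers[code] = p_cell * shares[..., c] * taei
        truth_aai[year] = CropGridStack(layers, target_geom, "aai", year, NODATA)

    # regional series and reference table derived from truth by aggregation
    rows = []
    for year, stack in truth_aai.items():
        total = stack.total()
        sums = np.bincount(idx.ravel(), weights=total.ravel(),
                           minlength=len(region_raster.region_ids))
        rows.extend((rid, year, float(s))
                    for rid, s in zip(region_raster.region_ids, sums))
    nuts2_series = pd.DataFrame(rows, columns=["region_id", "year", "taai_ha"])

    reported_n1 = set(nuts1_ids[: cfg.n_nuts1_reported])
    nuts2_series["parent_id"] = nuts2_series["region_id"].map(nuts1_of)
    at_nuts1 = nuts2_series[nuts2_series["parent_id"].isin(reported_n1)]
    at_nuts2 = nuts2_series[~nuts2_series["parent_id"].isin(reported_n1)]
    n1_rows = (at_nuts1.groupby(["parent_id", "year"], as_index=False)["taai_ha"]
               .sum().rename(columns={"parent_id": "region_id"}))
    aai_series = pd.concat(
        [n1_rows, at_nuts2[["region_id", "year", "taai_ha"]]],
        ignore_index=True).sort_values(["region_id", "year"]).reset_index(drop=True)

    ref_year = cfg.year_list[0]
    ref_rows = []
    ref_stack = truth_aai[ref_year]
    for code, arr in ref_stack.layers.items():
        sums = np.bincount(idx.ravel(), weights=arr.ravel(),
                           minlength=len(region_raster.region_ids))
        ref_rows.extend((rid, code, float(s))
                        for rid, s in zip(region_raster.region_ids, sums))
    crop_aai_ref = pd.DataFrame(ref_rows,
                                columns=["region_id", "crop_code", "aai_ha"])

    return WorldBundle(
        config=cfg, region_table=region_table, region_raster=region_raster,
        aai_series=aai_series, crop_aai_ref=crop_aai_ref,
        aei_fine_2005=fine_2005, aei_coarse_2010=coarse_2010,
        weight_grid=weight_grid, crop_share_grids=crop_share_grids,
        truth_aai=truth_aai, taei_1km_2010=taei_1km,
        target_geometry=target_geom, reference_year=ref_year,
    )


def make_survey_points(bundle: WorldBundle, n_points: int, year: int,
                       seed: int) -> pd.DataFrame:
    """Bernoulli point survey of the synthetic world.

    Cells with nonzero agricultural area are sampled uniformly without
    replacement; one point sits at each sampled cell's centre.  The
    point's crop follows the cell's growing-share distribution and it is
    marked irrigated (water-management code 1, else 5) with probability
    equal to the cell's irrigated fraction of that crop's growing area.
    All points carry the agricultural land-use code U111.
    """
    if year not in bundle.config.year_list:
        raise ValueError(f"year {year} outside the bundle's year range")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ga_stack = crop_growing_area(
        bundle.weight_grid, bundle.crop_share_grids[year])
    ga_total = ga_stack.total()
    eligible = np.argwhere(ga_total > 0)
    if n_points > len(eligible):
        raise ValueError(
            f"n_points={n_points} exceeds the {len(eligible)} cells with "
            "nonzero agricultural area"
        )
    chosen = eligible[rng.choice(len(eligible), size=n_points, replace=False)]
    geom = bundle.target_geometry
    codes = list(bundle.crop_share_grids[year])
    share_cube = np.stack([bundle.crop_share_grids[year][c].values
                           for c in codes], axis=-1)
    truth = bundle.truth_aai[year]

    rows = []
    for i, j in chosen:
        w = share_cube[i, j]
        probs = w / w.sum()
        c = int(rng.choice(len(codes), p=probs))
        code = codes[c]
        ga_c = ga_stack[code][i, j]
        frac = truth[code][i, j] / ga_c if ga_c > 0 else 0.0
        irrigated = rng.random() < min(frac, 1.0)
        rows.append((
            geom.x0 + (j + 0.5) * geom.cell_size,
            geom.y0 - (i + 0.5) * geom.cell_size,
            year, "U111", "", 1 if irrigated else 5, code,
        ))
    return pd.DataFrame(rows, columns=["x", "y", "year", "lu1", "lu2",
                                       "wm", "crop_code"])
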