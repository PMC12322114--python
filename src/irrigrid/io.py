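"""GeoTIFF and CSV plumbing.

Rasters travel as single-band float GeoTIFFs on the projected 1-km
European grid (EPSG:3035), with an explicit nodata tag; tables as CSV
with documented headers.  Output rasters follow the
``{CROP}_{IR|RF}_A_{YYYY}.tif`` naming convention, e.g.
``LMAIZ_IR_A_2010.tif`` for irrigated maize in 2010, plus
``Total_IR_A_{YYYY}.tif`` / ``Total_RF_A_{YYYY}.tif`` / ``UAA_{YYYY}.tif``
summary layers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grid import Grid, GridGeometry, RegionRaster

__all__ = [
    "read_grid", "write_grid", "output_name",
    "save_bundle", "load_bundle",
]

EPSG_3035 = 3035

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


def write_grid(grid: Grid, path: str | Path, float32: bool = False,
               epsg: int = EPSG_3035) -> Path:
    """Write a grid as a single-band GeoTIFF with CRS and nodata tags."""
    path = Path(path)
    g = grid.geometry
    values = grid.values.astype(np.float32 if float32 else np.float64)
    geokeys = (
        1, 1, 0, 3,          # version, revision; 3 keys follow
        1024, 0, 1, 1,       # model type: projected
        1025, 0, 1, 1,       # raster type: pixel is area
        3072, 0, 1, epsg,    # projected CRS code
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0), False),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x0, g.y0, 0.0), False),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys, False),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata)), False),
    ]
    tifffile.imwrite(path, values, extratags=extratags)
    return path


def read_grid(path: str | Path, units: str = "ha") -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_grid`.

    Fails explicitly when the georeferencing or nodata tags are absent.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        for code, what in ((_TAG_PIXEL_SCALE, "pixel scale"),
                           (_TAG_TIEPOINT, "tiepoint"),
                           (_TAG_GEO_KEYS, "CRS geo-keys"),
                           (_TAG_GDAL_NODATA, "nodata")):
            if code not in tags:
                raise ValueError(f"{path}: missing {what} tag ({code})")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells ({sx} x {sy})")
        tie = tags[_TAG_TIEPOINT].value
        x0 = tie[3] - tie[0] * sx
        y0 = tie[4] + tie[1] * sy
        nodata = float(tags[_TAG_GDAL_NODATA].value)
        values = page.asarray().astype(np.float64)
    geom = GridGeometry(x0, y0, sx, values.shape[0], values.shape[1])
    return Grid(values, geom, nodata, units)


def output_name(crop_code: str, kind: str, year: int) -> str:
    """Product file name: crop (or Total/UAA), irrigation flag, year."""
    if kind == "IR":
        return f"{crop_code}_IR_A_{year}.tif"
    if kind == "RF":
        return f"{crop_code}_RF_A_{year}.tif"
    if kind == "A":
        return f"{crop_code}_A_{year}.tif"
    if kind == "UAA":
        return f"UAA_{year}.tif"
    raise ValueError(f"unknown output kind {kind!r}")


# ---------------------------------------------------------------------------
# synthetic-world bundle serialization

def save_bundle(bundle, out_dir: str | Path) -> Path:
    """Serialize a WorldBundle as a directory of GeoTIFFs and CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(bundle.config)
    cfg["years"] = list(cfg["years"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    bundle.region_table.to_csv(out / "regions.csv", index=False)
    pd.DataFrame({"region_index": range(len(bundle.region_raster.region_ids)),
                  "region_id": bundle.region_raster.region_ids}
                 ).to_csv(out / "region_index.csv", index=False)
    bundle.aai_series.to_csv(out / "aai_series.csv", index=False,
                             float_format="%.17g")
    bundle.crop_aai_ref.to_csv(out / "crop_aai_ref.csv", index=False,
                               float_format="%.17g")

    rr = bundle.region_raster
    region_grid = Grid(np.where(rr.mask(), rr.indices.astype(np.float64), -9999.0),
                       rr.geometry, -9999.0, "index")
    write_grid(region_grid, out / "region_raster.tif")
    write_grid(bundle.aei_fine_2005, out / "aei_fine_2005.tif")
    write_grid(bundle.aei_coarse_2010, out / "aei_coarse_2010.tif")
    write_grid(bundle.weight_grid, out / "weight.tif")

    shares_dir = out / "shares"
    shares_dir.mkdir(exist_ok=True)
    for year, grids in bundle.crop_share_grids.items():
        for code, grid in grids.items():
            write_grid(grid, shares_dir / f"{code}_{year}.tif")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for year, stack in bundle.truth_aai.items():
        for code in stack.crop_codes:
            write_grid(stack.grid(code), truth_dir / f"{code}_{year}.tif")
    return out


def load_bundle(in_dir: str | Path):
    """Load a WorldBundle directory written by :func:`save_bundle`."""
    from .allocate import CropGridStack
    from .synthetic import WorldBundle, WorldConfig

    src = Path(in_dir)
    cfg_raw = yaml.safe_load((src / "config.yaml").read_text())
    cfg_raw["years"] = tuple(cfg_raw["years"])
    config = WorldConfig(**cfg_raw)

    region_table = pd.read_csv(src / "regions.csv").fillna({"parent_id": ""})
    region_ids = list(pd.read_csv(src / "region_index.csv")["region_id"])
    region_grid = read_grid(src / "region_raster.tif", "index")
    indices = np.where(region_grid.mask(),
                       region_grid.values, -1.0).astype(np.int64)
    region_raster = RegionRaster(indices, region_ids, region_grid.geometry)

    aai_series = pd.read_csv(src / "aai_series.csv",
                             float_precision="round_trip")
    crop_aai_ref = pd.read_csv(src / "crop_aai_ref.csv",
                               float_precision="round_trip")
    fine = read_grid(src / "aei_fine_2005.tif")
    coarse = read_grid(src / "aei_coarse_2010.tif")
    weight = read_grid(src / "weight.tif", "percent")

    years = config.year_list
    crop_codes = list(config.crop_codes)
    crop_share_grids = {
        year: {code: read_grid(src / "shares" / f"{code}_{year}.tif", "fraction")
               for code in crop_codes}
        for year in years
    }
    target_geom = region_grid.geometry
    truth_aai = {}
    for year in years:
        layers = {code: read_grid(src / "truth" / f"{code}_{year}.tif").values
                  for code in crop_codes}
        truth_aai[year] = CropGridStack(layers, target_geom, "aai", year)

    # re-derive the harmonized equipped-area grid from the serialized inputs
    from .harmonize import (aggregate_block_sum, change_ratio, harmonized_aei,
                            resample_bilinear)
    coarse_2005, _ = aggregate_block_sum(fine, config.coarse_factor)
    ratio, _ = change_ratio(coarse_2005, coarse, "inverted")
    taei = harmonized_aei(resample_bilinear(fine, target_geom),
                          resample_bilinear(ratio, target_geom))

    return WorldBundle(
        config=config, region_table=region_table, region_raster=region_raster,
        aai_series=aai_series, crop_aai_ref=crop_aai_ref,
        aei_fine_2005=fine, aei_coarse_2010=coarse, weight_grid=weight,
        crop_share_grids=crop_share_grids, truth_aai=truth_aai,
        taei_1km_2010=taei, target_geometry=target_geom,
        reference_year=years[0],
    )
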