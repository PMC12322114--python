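"""Per-cell crop-specific allocation of regional irrigated-area targets.

The 1-km equipped-area map is split across crops by the crop growing
shares, aggregated per NUTS2 region, and compared with the annual
regional crop targets to give one calibration coefficient per (region,
crop, year).  Every cell of a region is scaled by the same coefficient
(the uniform-irrigation-percentage assumption), which makes the regional
cell sums meet the targets exactly whenever nothing is clipped.

Two in-cell post-processing steps follow: a capacity cap (a 1-km cell
holds at most 100 ha, so crop totals above the cap are scaled down
proportionally) and a clamp of irrigated area to the crop growing area,
from which the rainfed complement is derived.  Clipped mass is never
redistributed to other cells; it is surfaced in diagnostics instead so
any conservation loss stays measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid, GridGeometry, RegionRaster

__all__ = [
    "CropGridStack",
    "uaa_grid",
    "crop_growing_area",
    "crop_aei",
    "zonal_sum",
    "calibration",
    "allocate_aai",
    "apply_cell_cap",
    "derive_rainfed",
]


@dataclass
class CropGridStack:
    """Per-crop single-band layers sharing one geometry.

    ``kind`` declares the semantics: growing_area, aei, aai or rainfed;
    all values are hectares.
    """

    layers: dict[str, np.ndarray]
    geometry: GridGeometry
    kind: str
    year: int | None = None
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        for code, arr in self.layers.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != self.geometry.shape:
                raise ValueError(f"layer {code!r} shape mismatch")
            self.layers[code] = arr

    @property
    def crop_codes(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, code: str) -> np.ndarray:
        return self.layers[code]

    def grid(self, code: str, units: str = "ha") -> Grid:
        return Grid(self.layers[code], self.geometry, self.nodata, units)

    def total(self) -> np.ndarray:
        """Cell-wise sum over crops, nodata-aware."""
        out = np.zeros(self.geometry.shape)
        bad = np.zeros(self.geometry.shape, dtype=bool)
        for arr in self.layers.values():
            m = arr == self.nodata
            bad |= m
            out += np.where(m, 0.0, arr)
        return np.where(bad, self.nodata, out)

    def copy(self) -> "CropGridStack":
        return CropGridStack({c: a.copy() for c, a in self.layers.items()},
                             self.geometry, self.kind, self.year, self.nodata)


def uaa_grid(weight_grid: Grid, cell_area_ha: float | None = None) -> Grid:
    """Utilized agricultural area per cell from the percent weight layer.

    Weights above 100 % are capped at 100 % so the layer can be read as an
    area fraction of the cell.
    """
    if cell_area_ha is None:
        cell_area_ha = weight_grid.geometry.cell_area_ha()
    w = weight_grid.values
    if np.any((w < 0) & weight_grid.mask()):
        raise ValueError("negative cell weights")
    uaa = np.where(weight_grid.mask(),
                   np.minimum(w, 100.0) / 100.0 * cell_area_ha,
                   weight_grid.nodata)
    return Grid(uaa, weight_grid.geometry, weight_grid.nodata, "ha")


def crop_growing_area(weight_grid: Grid, crop_share_grids: dict[str, Grid],
                      cell_area_ha: float | None = None) -> CropGridStack:
    """Crop growing area: capped UAA times the per-crop growing shares."""
    uaa = uaa_grid(weight_grid, cell_area_ha)
    layers = {}
    for code, share in crop_share_grids.items():
        if share.geometry != weight_grid.geometry:
            raise ValueError(f"share grid {code!r} geometry mismatch")
        s = share.values
        if np.any((s < 0) & share.mask()):
            raise ValueError(f"negative growing share for {code!r}")
        valid = uaa.mask() & share.mask()
        layers[code] = np.where(valid, uaa.filled(0.0) * share.filled(0.0),
                                weight_grid.nodata)
    return CropGridStack(layers, weight_grid.geometry, "growing_area",
                         nodata=weight_grid.nodata)


def crop_aei(crop_share_grids: dict[str, Grid], taei_1km: Grid) -> CropGridStack:
    """Crop-specific equipped area: growing share times total equipped area."""
    layers = {}
    for code, share in crop_share_grids.items():
        if share.geometry != taei_1km.geometry:
            raise ValueError(f"share grid {code!r} geometry mismatch")
        valid = share.mask() & taei_1km.mask()
        layers[code] = np.where(valid, share.filled(0.0) * taei_1km.filled(0.0),
                                taei_1km.nodata)
    return CropGridStack(layers, taei_1km.geometry, "aei", nodata=taei_1km.nodata)


def zonal_sum(stack: CropGridStack, regions: RegionRaster) -> pd.DataFrame:
    """Exact per-region per-crop sums over non-nodata region cells.

    Returns (region_id, crop_code, total_ha); every region appears, empty
    regions with total 0.
    """
    if regions.geometry != stack.geometry:
        raise ValueError("region raster geometry mismatch")
    idx = regions.indices
    inside = regions.mask()
    nreg = len(regions.region_ids)
    rows = []
    for code, arr in stack.layers.items():
        valid = inside & (arr != stack.nodata)
        sums = np.bincount(idx[valid], weights=arr[valid], minlength=nreg)
        rows.extend((rid, code, float(s))
                    for rid, s in zip(regions.region_ids, sums))
    return pd.DataFrame(rows, columns=["region_id", "crop_code", "total_ha"])


def calibration(targets: pd.DataFrame, regional_aei: pd.DataFrame) -> pd.DataFrame:
    """Calibration coefficients: percent of regional target to regional AEI.

    Parameters
    ----------
    targets
        (region_id, crop_code, year, aai_ha) annual regional crop targets.
    regional_aei
        (region_id, crop_code, total_ha) zonal sums of crop-specific AEI.

    Returns
    -------
    (region_id, crop_code, year, coeff_pct, regional_aei_ha,
    regional_target_ha, flagged).  Coefficients are not clipped at 100 %;
    rows where the region holds no equipped area but a positive target are
    flagged with coefficient 0, so the target mass stays unallocated.
    """
    if (targets["aai_ha"] < 0).any() or (regional_aei["total_ha"] < 0).any():
        raise ValueError("negative calibration inputs")
    merged = targets.merge(regional_aei, on=["region_id", "crop_code"], how="left")
    if merged["total_ha"].isna().any():
        bad = merged.loc[merged["total_ha"].isna(), ["region_id", "crop_code"]]
        raise ValueError(f"missing regional AEI for {bad.to_records(index=False)}")
    aei = merged["total_ha"].to_numpy()
    tgt = merged["aai_ha"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = np.where(aei > 0, 100.0 * tgt / np.where(aei > 0, aei, 1.0), 0.0)
    merged["coeff_pct"] = coeff
    merged["flagged"] = (aei == 0) & (tgt > 0)
    merged = merged.rename(columns={"total_ha": "regional_aei_ha",
                                    "aai_ha": "regional_target_ha"})
    return merged[["region_id", "crop_code", "year", "coeff_pct",
                   "regional_aei_ha", "regional_target_ha", "flagged"]]


def allocate_aai(aei_stack: CropGridStack, calib: pd.DataFrame,
                 regions: RegionRaster, year: int) -> CropGridStack:
    """Uncapped crop irrigated area: regional coefficient times cell AEI.

    Every cell of a region gets the same coefficient; cells outside all
    regions become nodata.
    """
    if regions.geometry != aei_stack.geometry:
        raise ValueError("region raster geometry mismatch")
    cal = calib[calib["year"] == year]
    lut = {(r, c): p for r, c, p in
           zip(cal["region_id"], cal["crop_code"], cal["coeff_pct"])}
    inside = regions.mask()
    layers = {}
    for code, aei in aei_stack.layers.items():
        try:
            coeffs = np.array([lut[(rid, code)] for rid in regions.region_ids])
        except KeyError as exc:
            raise ValueError(f"no calibration coefficient for {exc.args[0]}") from None
        coeff_map = coeffs[np.where(inside, regions.indices, 0)]
        valid = inside & (aei != aei_stack.nodata)
        layers[code] = np.where(valid, coeff_map / 100.0 * np.where(valid, aei, 0.0),
                                aei_stack.nodata)
    return CropGridStack(layers, aei_stack.geometry, "aai", year, aei_stack.nodata)


def apply_cell_cap(aai_stack: CropGridStack, cap_ha: float | None = None,
                   regions: RegionRaster | None = None
                   ) -> tuple[CropGridStack, pd.DataFrame]:
    """Scale down cells whose crop-summed irrigated area exceeds the capacity.

    Where the cell total exceeds ``cap_ha`` (default: the cell area, 100 ha
    for a 1-km cell), every crop layer is multiplied by ``cap / total``, so
    the total equals the cap and crop ratios are preserved.  Returns the
    capped stack and a diagnostics table of clipped mass (per region when a
    region raster is given, else grid-wide).
    """
    if cap_ha is None:
        cap_ha = aai_stack.geometry.cell_area_ha()
    if cap_ha <= 0:
        raise ValueError("cell capacity must be positive")
    total = aai_stack.total()
    valid = total != aai_stack.nodata
    over = valid & (total > cap_ha)
    scale = np.where(over, cap_ha / np.where(over, total, 1.0), 1.0)
    out = aai_stack.copy()
    for code, arr in out.layers.items():
        m = arr != out.nodata
        arr[m] = arr[m] * scale[m]
    clipped = np.where(over, total - cap_ha, 0.0)
    if regions is not None:
        sums = np.bincount(regions.indices[regions.mask()],
                           weights=clipped[regions.mask()],
                           minlength=len(regions.region_ids))
        diag = pd.DataFrame({"region_id": regions.region_ids,
                             "clipped_ha": sums,
                             "n_cells_capped": np.bincount(
                                 regions.indices[regions.mask()],
                                 weights=over[regions.mask()].astype(float),
                                 minlength=len(regions.region_ids)).astype(int)})
    else:
        diag = pd.DataFrame({"region_id": ["<all>"],
                             "clipped_ha": [float(clipped.sum())],
                             "n_cells_capped": [int(over.sum())]})
    return out, diag


def derive_rainfed(growing: CropGridStack, aai_capped: CropGridStack
                   ) -> tuple[CropGridStack, CropGridStack, pd.DataFrame]:
    """Clamp irrigated area to the growing area and derive the rainfed rest.

    Returns (rainfed stack, final irrigated stack, diagnostics of clamped
    mass per crop).  The identity irrigated + rainfed = growing area holds
    exactly everywhere both inputs are valid.
    """
    if growing.geometry != aai_capped.geometry:
        raise ValueError("geometry mismatch between growing and irrigated stacks")
    rain, final = {}, {}
    diag_rows = []
    for code in aai_capped.crop_codes:
        ga = growing.layers[code]
        aai = aai_capped.layers[code]
        valid = (ga != growing.nodata) & (aai != aai_capped.nodata)
        clamped = np.where(valid, np.minimum(aai, ga), aai_capped.nodata)
        rf = np.where(valid, ga - np.where(valid, clamped, 0.0), aai_capped.nodata)
        final[code] = clamped
        rain[code] = rf
        excess = np.where(valid, np.maximum(aai - ga, 0.0), 0.0)
        diag_rows.append((code, float(excess.sum()), int((excess > 0).sum())))
    diag = pd.DataFrame(diag_rows, columns=["crop_code", "clamped_ha", "n_cells_clamped"])
    year = aai_capped.year
    return (CropGridStack(rain, growing.geometry, "rainfed", year, aai_capped.nodata),
            CropGridStack(final, growing.geometry, "aai", year, aai_capped.nodata),
            diag)
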