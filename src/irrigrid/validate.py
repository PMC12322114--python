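"""Agreement between point surveys and gridded irrigated-area maps.

Survey points in the style of the European land-use/cover area frame
survey carry land-use codes (U111 agriculture, U112 fallow) and a water
management code: 1 irrigation, 2 potential irrigation, 3 drainage,
4 irrigation and drainage, 5 no visible water management, 8 not
relevant.  Points with codes 1 and 4 count as irrigated (optionally 2 as
well).  Points and raster are both aggregated to square comparison
blocks; per block the point-side irrigated percentage is
``100 * NI / NT`` (irrigated over total investigated points) and the
raster side is ``100 * TAAI / TA`` (summed irrigated area over block
area).  Blocks irrigated on both sides above a small threshold (default
0.3 %, inclusive) are retained, and per-crop agreement is summarised by
the Pearson correlation and the ordinary-least-squares slope of the
raster side on the point side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid, GridGeometry
from .allocate import CropGridStack

__all__ = [
    "VALID_WM_CODES",
    "classify_survey_points",
    "block_irrigated_percentage_points",
    "block_irrigated_percentage_raster",
    "paired_filter",
    "agreement_stats",
]

VALID_WM_CODES = frozenset({1, 2, 3, 4, 5, 8})
_AGRI_LU = frozenset({"U111", "U112"})


def classify_survey_points(points: pd.DataFrame,
                           include_potential: bool = False) -> pd.DataFrame:
    """Filter survey points to agricultural land and flag irrigated ones.

    Keeps rows whose primary or secondary land use is agriculture (U111)
    or fallow (U112) and adds a boolean ``irrigated`` column: water
    management code 1 or 4 (plus 2 when ``include_potential``).
    """
    unknown = sorted(set(points["wm"]) - VALID_WM_CODES)
    if unknown:
        raise ValueError(f"unknown water-management code(s): {unknown}")
    keep = points["lu1"].isin(_AGRI_LU) | points["lu2"].isin(_AGRI_LU)
    out = points.loc[keep].copy()
    irrigated_codes = {1, 4} | ({2} if include_potential else set())
    out["irrigated"] = out["wm"].isin(irrigated_codes)
    return out.reset_index(drop=True)


def _block_index(x: np.ndarray, y: np.ndarray, geometry: GridGeometry,
                 block_km: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block (row, col) of each point; half-open intervals, origin top-left."""
    size = block_km * 1000.0
    col = np.floor((np.asarray(x) - geometry.x0) / size).astype(np.int64)
    row = np.floor((geometry.y0 - np.asarray(y)) / size).astype(np.int64)
    extent_x = geometry.ncols * geometry.cell_size
    extent_y = geometry.nrows * geometry.cell_size
    inside = ((np.asarray(x) >= geometry.x0) & (np.asarray(x) < geometry.x0 + extent_x)
              & (np.asarray(y) <= geometry.y0) & (np.asarray(y) > geometry.y0 - extent_y))
    return row, col, inside


def block_irrigated_percentage_points(points: pd.DataFrame, geometry: GridGeometry,
                                      block_km: float,
                                      per_crop: bool = True) -> pd.DataFrame:
    """Point-side irrigated percentage per comparison block.

    ``points`` must carry x, y, crop_code and the ``irrigated`` flag from
    :func:`classify_survey_points`.  Points outside the grid extent are
    dropped; blocks with no points are omitted.  Returns
    (block_row, block_col[, crop_code], ip_pct, n_points).
    """
    row, col, inside = _block_index(points["x"].to_numpy(),
                                    points["y"].to_numpy(), geometry, block_km)
    df = points.loc[inside].copy()
    df["block_row"] = row[inside]
    df["block_col"] = col[inside]
    keys = ["block_row", "block_col"] + (["crop_code"] if per_crop else [])
    grouped = df.groupby(keys)["irrigated"].agg(["sum", "count"]).reset_index()
    grouped["ip_pct"] = 100.0 * grouped["sum"] / grouped["count"]
    grouped = grouped.rename(columns={"count": "n_points"}).drop(columns="sum")
    return grouped


def block_irrigated_percentage_raster(aai, block_km: float,
                                      crop_code: str | None = None) -> pd.DataFrame:
    """Raster-side irrigated percentage per comparison block.

    ``aai`` is a Grid or a CropGridStack (then every crop layer is
    reported).  The block size must be an integer multiple of the cell
    size; partial edge blocks use the cell area they actually cover as
    the denominator.  Nodata cells contribute area but no irrigated mass.
    """
    if isinstance(aai, CropGridStack):
        frames = []
        for code in aai.crop_codes:
            f = block_irrigated_percentage_raster(aai.grid(code), block_km, code)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    geometry = aai.geometry
    size_cells = block_km * 1000.0 / geometry.cell_size
    if abs(size_cells - round(size_cells)) > 1e-9:
        raise ValueError("block size must be an integer multiple of the cell size")
    k = int(round(size_cells))
    cell_area = geometry.cell_area_ha()
    nbr = math.ceil(geometry.nrows / k)
    nbc = math.ceil(geometry.ncols / k)
    v = aai.filled(0.0)
    rows = []
    for bi in range(nbr):
        for bj in range(nbc):
            sl = v[bi * k:(bi + 1) * k, bj * k:(bj + 1) * k]
            taai = float(sl.sum())
            ta = sl.size * cell_area
            rec = {"block_row": bi, "block_col": bj,
                   "ip_pct": 100.0 * taai / ta}
            if crop_code is not None:
                rec["crop_code"] = crop_code
            rows.append(rec)
    return pd.DataFrame(rows)


def paired_filter(a: pd.DataFrame, b: pd.DataFrame,
                  min_ip_pct: float = 0.3) -> pd.DataFrame:
    """Pair block tables and keep blocks irrigated on both sides.

    Blocks must appear on both sides with irrigated percentage at or above
    the threshold (inclusive) on both.  Returns the merged table with
    ``ip_a`` and ``ip_b`` columns.
    """
    keys = [c for c in ("block_row", "block_col", "crop_code", "year")
            if c in a.columns and c in b.columns]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    merged = merged.rename(columns={"ip_pct_a": "ip_a", "ip_pct_b": "ip_b"})
    keep = (merged["ip_a"] >= min_ip_pct) & (merged["ip_b"] >= min_ip_pct)
    return merged.loc[keep].reset_index(drop=True)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def agreement_stats(paired: pd.DataFrame, per_crop: bool = True) -> pd.DataFrame:
    """Pearson r, OLS slope of b on a, and significance per crop.

    The two-sided p-value comes from the correlation's t statistic with
    n - 2 degrees of freedom.  Groups with fewer than 3 blocks or zero
    variance on either side are flagged and report NaN statistics.
    """
    groups = (paired.groupby("crop_code") if per_crop and "crop_code" in paired
              else [(None, paired)])
    rows = []
    for code, df in groups:
        a = df["ip_a"].to_numpy(dtype=float)
        b = df["ip_b"].to_numpy(dtype=float)
        n = len(df)
        rec = {"crop_code": code, "n_blocks": n, "pearson_r": np.nan,
               "slope": np.nan, "p_value": np.nan, "stars": "ns", "flagged": True}
        if n >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
            res = stats.linregress(a, b)
            rec.update(pearson_r=res.rvalue, slope=res.slope,
                       p_value=res.pvalue, stars=_stars(res.pvalue),
                       flagged=False)
        rows.append(rec)
    return pd.DataFrame(rows)
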