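"""Harmonize a fine 2005 and a coarse 2010 equipped-area raster to 1 km.

The area equipped for irrigation (AEI) is available fine-grained for 2005
and coarse-grained for 2010.  The two are combined by (1) block-summing
the fine map to the coarse lattice, (2) forming a per-coarse-cell change
ratio between the two epochs, (3) bilinearly resampling both the ratio
field and the fine 2005 map to the 1-km target grid, and (4) multiplying
the two, which yields a 1-km AEI estimate for 2010.

The change ratio supports two orientations.  ``inverted`` (default)
multiplies the 2005 map by the 2010/2005 ratio, which conserves the
coarse 2010 totals when the ratio field is spatially constant;
``as_printed`` uses the 2005/2010 ratio instead and is retained for
literal reproduction of the published formulas, which state that
orientation despite its inconsistent units when re-multiplied.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid, GridGeometry

__all__ = [
    "aggregate_block_sum",
    "change_ratio",
    "resample_bilinear",
    "harmonized_aei",
]


def aggregate_block_sum(fine: Grid, factor: int) -> tuple[Grid, int]:
    """Sum ``factor x factor`` blocks of a fine grid onto the coarse lattice.

    Nodata members are treated as zero; the count of such cells is
    returned as a diagnostic alongside the coarse grid.
    """
    if factor <= 0:
        raise ValueError("block factor must be positive")
    geom = fine.geometry.block_geometry(factor)  # raises on non-divisible shape
    nodata_count = int(np.count_nonzero(~fine.mask()))
    v = fine.filled(0.0)
    coarse = v.reshape(geom.nrows, factor, geom.ncols, factor).sum(axis=(1, 3))
    return Grid(coarse, geom, fine.nodata, fine.units), nodata_count


def change_ratio(coarse_2005: Grid, coarse_2010: Grid,
                 orientation: str = "inverted") -> tuple[Grid, np.ndarray]:
    """Per-cell epoch change ratio in percent, plus a zero-denominator flag mask.

    ``as_printed``: 100 * v2005 / v2010; ``inverted``: 100 * v2010 / v2005.
    Cells whose denominator is zero (or nodata) get ratio 0 and are flagged,
    so no equipped area survives there downstream.
    """
    if coarse_2005.geometry != coarse_2010.geometry:
        raise ValueError("change_ratio requires identical grid geometry")
    if orientation == "as_printed":
        num, den = coarse_2005, coarse_2010
    elif orientation == "inverted":
        num, den = coarse_2010, coarse_2005
    else:
        raise ValueError(f"unknown ratio orientation {orientation!r}")
    n = num.filled(0.0)
    d = den.filled(0.0)
    flagged = d == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(flagged, 0.0, 100.0 * n / np.where(flagged, 1.0, d))
    return Grid(ratio, coarse_2005.geometry, coarse_2005.nodata, "percent"), flagged


def resample_bilinear(src: Grid, target: GridGeometry) -> Grid:
    """Bilinear resampling of ``src`` onto the ``target`` cell-centre lattice.

    Each target cell centre is mapped into the source's fractional index
    space and assigned the weighted average of the four surrounding source
    cell centres.  Outside the outer centre lattice, coordinates clamp to
    the boundary centres (edge replication).  If any of the four
    neighbours is nodata the output cell is nodata.
    """
    nrows, ncols = src.shape
    if nrows < 2 or ncols < 2:
        raise ValueError("bilinear resampling requires a source of at least 2x2 cells")
    g = src.geometry
    tx, ty = target.cell_centres()
    # fractional index of the target centre in source-centre space
    fj = (tx - g.x0) / g.cell_size - 0.5
    fi = (g.y0 - ty) / g.cell_size - 0.5
    fj = np.clip(fj, 0.0, ncols - 1.0)
    fi = np.clip(fi, 0.0, nrows - 1.0)
    j0 = np.minimum(np.floor(fj).astype(np.int64), ncols - 2)
    i0 = np.minimum(np.floor(fi).astype(np.int64), nrows - 2)
    dx = fj - j0
    dy = fi - i0
    v = src.values
    v00 = v[i0, j0]
    v01 = v[i0, j0 + 1]
    v10 = v[i0 + 1, j0]
    v11 = v[i0 + 1, j0 + 1]
    out = ((1 - dx) * (1 - dy) * v00 + dx * (1 - dy) * v01
           + (1 - dx) * dy * v10 + dx * dy * v11)
    bad = ((v00 == src.nodata) | (v01 == src.nodata)
           | (v10 == src.nodata) | (v11 == src.nodata))
    out = np.where(bad, src.nodata, out)
    return Grid(out, target, src.nodata, src.units)


def harmonized_aei(fine_2005_on_target: Grid, ratio_on_target: Grid) -> Grid:
    """1-km equipped area for 2010: change ratio (percent) times the 2005 map."""
    if fine_2005_on_target.geometry != ratio_on_target.geometry:
        raise ValueError("harmonized_aei requires identical grid geometry")
    valid = fine_2005_on_target.mask() & ratio_on_target.mask()
    out = np.where(
        valid,
        ratio_on_target.filled(0.0) / 100.0 * fine_2005_on_target.filled(0.0),
        fine_2005_on_target.nodata,
    )
    return Grid(out, fine_2005_on_target.geometry,
                fine_2005_on_target.nodata, fine_2005_on_target.units)
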