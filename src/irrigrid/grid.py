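"""Planar single-band raster container and block/zonal primitives.

All grids live on a projected, north-up, square-cell lattice (the 1-km
European grid uses EPSG:3035).  Cell ``(i, j)`` (0-based, row 0 at the top)
has its centre at ``x = x0 + (j + 0.5) * cell_size`` and
``y = y0 - (i + 0.5) * cell_size``; cell extents are half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridGeometry", "Grid", "RegionRaster"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Affine placement of a north-up square-cell raster.

    Parameters
    ----------
    x0, y0
        Projected coordinates of the outer corner of cell (0, 0)
        (top-left corner of the raster).
    cell_size
        Cell edge length in metres (> 0).
    nrows, ncols
        Raster shape.
    """

    x0: float
    y0: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid must have positive dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def block_geometry(self, factor: int) -> "GridGeometry":
        """Geometry of the coarse grid obtained by factor x factor aggregation."""
        if self.nrows % factor or self.ncols % factor:
            raise ValueError(
                f"grid shape {self.shape} not divisible by block factor {factor}"
            )
        return GridGeometry(
            self.x0, self.y0, self.cell_size * factor,
            self.nrows // factor, self.ncols // factor,
        )

    def cell_area_ha(self) -> float:
        """Cell area in hectares (1 ha = 10^4 m^2)."""
        return self.cell_size ** 2 / 1e4


@dataclass
class Grid:
    """A single-band float raster with an explicit nodata sentinel.

    ``values`` is always float64; nodata cells carry the sentinel value and
    must be masked out of arithmetic by callers (helpers below propagate it).
    """

    values: np.ndarray
    geometry: GridGeometry
    nodata: float = DEFAULT_NODATA
    units: str = "ha"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced by ``fill``."""
        return np.where(self.mask(), self.values, fill)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Grid":
        return Grid(values, self.geometry, self.nodata,
                    self.units if units is None else units)

    def same_geometry(self, other: "Grid") -> bool:
        return self.geometry == other.geometry


@dataclass
class RegionRaster:
    """Cell-to-region membership on the target grid.

    ``indices`` holds 0-based positions into ``region_ids`` (NUTS2 level);
    cells outside every region carry -1.
    """

    indices: np.ndarray
    region_ids: list[str]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.shape != self.geometry.shape:
            raise ValueError("region raster shape mismatch")
        if self.indices.max(initial=-1) >= len(self.region_ids):
            raise ValueError("region index out of range")

    def mask(self) -> np.ndarray:
        return self.indices >= 0

    def region_mask(self, region_id: str) -> np.ndarray:
        return self.indices == self.region_ids.index(region_id)
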