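"""Georeferenced grids and rasters.

All 2D products in the pipeline (orthoimages, binary affection masks,
truth masks, percent grids) live on a north-up regular grid in a
projected coordinate system with units of meters.  ``GridSpec`` holds
the georeferencing; ``GeoRaster`` couples it with pixel data.

Conventions
-----------
* ``(origin_x, origin_y)`` is the map coordinate of the *outer* corner
  of pixel (0, 0), i.e. the north-west corner of the raster.
* Row index increases southward, column index eastward (north-up).
* Polygon membership and point-in-cell tests are decided at the pixel
  center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "GeoRaster"]


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a north-up regular raster grid.

    Parameters
    ----------
    origin_x, origin_y
        Map coordinates (m) of the outer (north-west) corner of pixel
        ``(0, 0)``.
    pixel_size
        Ground sample distance in meters (square pixels).
    n_rows, n_cols
        Raster shape.
    crs_id
        Free-text coordinate reference system label; never interpreted.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_center(self, row, col):
        """Map coordinates of pixel centers (vectorized)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional (row, col) of map coordinates; floor() gives the
        containing pixel."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.origin_x) / self.pixel_size - 0.5
        row = (self.origin_y - y) / self.pixel_size - 0.5
        return row, col

    def containing_pixel(self, x, y):
        """Integer (row, col) of the pixel whose area contains (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_size).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.pixel_size).astype(np.int64)
        return row, col

    def center_coords(self):
        """1-D arrays of x (per column) and y (per row) pixel-center
        coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return x, y

    def same_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


@dataclass
class GeoRaster:
    """Raster data on a :class:`GridSpec`.

    ``data`` is ``(n_rows, n_cols)`` for single-band rasters (binary
    masks, percent grids) or ``(n_rows, n_cols, 3)`` uint8 for RGB.
    Missing data is expressed through ``nodata`` (single band; compared
    by value) or through the boolean ``valid`` mask (RGB; True where the
    pixel carries data).  A single-band raster may carry both, in which
    case they must agree.
    """

    grid: GridSpec
    data: np.ndarray
    nodata: float | int | None = None
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape[:2] != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape[:2]} does not match grid {self.grid.shape}"
            )
        if self.data.ndim == 3 and self.data.shape[2] != 3:
            raise ValueError("multi-band rasters must have exactly 3 (RGB) bands")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("valid mask shape does not match grid")

    @property
    def is_rgb(self) -> bool:
        return self.data.ndim == 3

    def valid_mask(self) -> np.ndarray:
        """Boolean mask, True where the pixel carries data."""
        if self.valid is not None:
            return self.valid
        if self.nodata is None:
            return np.ones(self.grid.shape, dtype=bool)
        if self.is_rgb:  # nodata on RGB only meaningful with explicit mask
            return np.ones(self.grid.shape, dtype=bool)
        data = self.data
        if np.issubdtype(data.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(data)
        return data != self.nodata

    def copy(self) -> "GeoRaster":
        return GeoRaster(
            self.grid,
            self.data.copy(),
            nodata=self.nodata,
            valid=None if self.valid is None else self.valid.copy(),
        )
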