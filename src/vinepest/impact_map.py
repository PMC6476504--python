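"""1 m² impact and canopy-cover grids, plot summaries and grade maps.

The binary affection raster (and the vegetation mask, for canopy
cover) is aggregated onto a coarse square grid: each cell's value is
100 × the mean of its binary pixels — the percentage of affected (or
canopy) surface in that cell.  Plot-level percentages are the
pixel-weighted means of the grids, and the ratio affected% / canopy%
is the affected fraction of the canopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GeoRaster, GridSpec
from .geomatic_io import MASK_NODATA

__all__ = ["PercentGrid", "grid_aggregate", "plot_summary", "grade_map",
           "impact_histogram"]


@dataclass
class PercentGrid:
    """Coarse grid of percentages with per-cell considered-pixel counts.

    ``values`` is (rows, cols) float with NaN for cells without any
    considered pixel; ``counts`` holds the number of considered source
    pixels per cell.  The cell grid is anchored at the source raster
    origin; edge cells may be partial (their counts say so).
    """

    grid: GridSpec  # cell grid (pixel_size = cell size in m)
    values: np.ndarray
    counts: np.ndarray

    def as_raster(self) -> GeoRaster:
        return GeoRaster(self.grid, self.values, nodata=np.nan)

    def weighted_mean(self) -> float:
        """Pixel-weighted plot mean of the cell percentages."""
        w = self.counts.astype(np.float64)
        ok = w > 0
        if not np.any(ok):
            raise ValueError("percent grid has no considered pixels")
        return float((self.values[ok] * w[ok]).sum() / w[ok].sum())


def grid_aggregate(
    binary: GeoRaster,
    cell_size: float = 1.0,
    considered: GeoRaster | None = None,
) -> PercentGrid:
    """Aggregate a binary raster onto square cells of ``cell_size`` m:
    value = 100 × mean of the cell's considered binary pixels."""
    px = binary.grid.pixel_size
    if cell_size < px:
        raise ValueError("cell_size must be at least one pixel")
    valid = binary.valid_mask()
    if considered is not None:
        if not considered.grid.same_grid(binary.grid):
            raise ValueError("considered mask on a different grid")
        valid = valid & (considered.data == 1) & considered.valid_mask()

    n_rows, n_cols = binary.grid.shape
    # cell index of each pixel, by pixel-center coordinate
    xs, ys = binary.grid.center_coords()
    ci = np.floor((xs - binary.grid.origin_x) / cell_size).astype(np.int64)
    ri = np.floor((binary.grid.origin_y - ys) / cell_size).astype(np.int64)
    out_rows, out_cols = int(ri.max()) + 1, int(ci.max()) + 1
    cell_of_pixel = ri[:, None] * out_cols + ci[None, :]

    flat_cell = cell_of_pixel[valid]
    flat_val = (binary.data[valid] == 1).astype(np.float64)
    n_cells = out_rows * out_cols
    counts = np.bincount(flat_cell, minlength=n_cells)
    sums = np.bincount(flat_cell, weights=flat_val, minlength=n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, 100.0 * sums / np.maximum(counts, 1), np.nan)
    cell_grid = GridSpec(
        origin_x=binary.grid.origin_x,
        origin_y=binary.grid.origin_y,
        pixel_size=cell_size,
        n_rows=out_rows,
        n_cols=out_cols,
        crs_id=binary.grid.crs_id,
    )
    return PercentGrid(
        cell_grid,
        values.reshape(out_rows, out_cols),
        counts.reshape(out_rows, out_cols),
    )


def plot_summary(
    impact: PercentGrid,
    canopy: PercentGrid | None = None,
    histogram_bins: tuple[float, ...] = (0, 5, 10, 25, 50, 75, 100),
) -> dict:
    """Plot-level summary: affected-area %, canopy-cover %, affected
    fraction of canopy (= 100 · affected% / canopy%) and the histogram
    of per-cell impact values."""
    affected_pct = impact.weighted_mean()
    out: dict = {
        "affected_area_pct": affected_pct,
        "histogram_bin_edges": list(histogram_bins),
        "histogram_counts": impact_histogram(impact, histogram_bins),
        "n_cells": int((impact.counts > 0).sum()),
    }
    if canopy is not None:
        if not canopy.grid.same_grid(impact.grid):
            raise ValueError("impact and canopy grids are not aligned")
        canopy_pct = canopy.weighted_mean()
        out["canopy_cover_pct"] = canopy_pct
        if canopy_pct == 0:
            out["affected_fraction_of_canopy_pct"] = None
            out["canopy_absent"] = True
        else:
            out["affected_fraction_of_canopy_pct"] = 100.0 * affected_pct / canopy_pct
    return out


def impact_histogram(
    grid: PercentGrid, bin_edges: tuple[float, ...]
) -> list[int]:
    vals = grid.values[grid.counts > 0]
    counts, _ = np.histogram(vals, bins=np.asarray(bin_edges, dtype=float))
    return [int(c) for c in counts]


def grade_map(impact: PercentGrid, breaks: tuple[float, ...] = (25.0, 50.0, 75.0)) -> GeoRaster:
    """Thematic grade raster: cell value v gets grade g when v falls in
    the half-open interval [breaks[g-2], breaks[g-1]); grades run 1 to
    len(breaks)+1 (default four grades with quartile breaks)."""
    br = np.asarray(breaks, dtype=float)
    if br.ndim != 1 or len(br) < 1 or np.any(np.diff(br) <= 0):
        raise ValueError("breaks must be strictly increasing")
    if br.min() <= 0 or br.max() >= 100:
        raise ValueError("breaks must lie strictly inside (0, 100)")
    grades = np.full(impact.grid.shape, MASK_NODATA, dtype=np.uint8)
    ok = impact.counts > 0
    grades[ok] = np.searchsorted(br, impact.values[ok], side="right") + 1
    return GeoRaster(impact.grid, grades, nodata=MASK_NODATA)
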