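"""Vegetation-only orthoimage: stamp vegetation-classified points onto
the orthoimage grid and blank everything else.

The original workflow regenerated an orthomosaic from the vegetation
points alone; here the existing orthoimage is masked instead, which
leaves identical radiometry wherever vegetation exists — exactly what
the per-pixel classifier consumes — without re-running orthomosaic
rendering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk

from .grids import GeoRaster, GridSpec
from .geomatic_io import MASK_NODATA
from .pointcloud import CLASS_MEDIUM_VEGETATION, PointCloud

__all__ = ["VegetationMask", "points_to_mask", "apply_mask"]

log = logging.getLogger(__name__)


@dataclass
class VegetationMask:
    """Binary vegetation-support mask on the orthoimage grid."""

    raster: GeoRaster
    splat_radius: float

    @property
    def grid(self) -> GridSpec:
        return self.raster.grid

    def as_bool(self) -> np.ndarray:
        return self.raster.data == 1


def points_to_mask(
    cloud: PointCloud,
    grid: GridSpec,
    splat_radius: float,
    vegetation_class: int = CLASS_MEDIUM_VEGETATION,
    close_gaps: bool = False,
    closing_radius: int = 1,
) -> VegetationMask:
    """Mark every pixel whose center lies within ``splat_radius`` (m) of
    a vegetation-classified point; radius 0 marks only the containing
    pixel.

    ``close_gaps`` applies one binary closing pass (disk of
    ``closing_radius`` px) to bridge gaps where point density
    undershoots pixel density; unlike a larger splat radius, closing
    does not push the mask boundary beyond the outermost points.
    """
    if cloud.classification is None:
        raise ValueError("cloud carries no classification; run the ground filter first")
    if splat_radius < 0:
        raise ValueError("splat_radius must be >= 0")
    veg = cloud.classification == vegetation_class
    mask = np.zeros(grid.shape, dtype=bool)
    if not np.any(veg):
        log.warning("no vegetation-class points; mask is empty")
        return VegetationMask(
            GeoRaster(grid, mask.astype(np.uint8), nodata=MASK_NODATA), splat_radius
        )
    px = grid.pixel_size
    x, y = cloud.x[veg], cloud.y[veg]
    if splat_radius == 0:
        row, col = grid.containing_pixel(x, y)
        ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
        mask[row[ok], col[ok]] = True
    else:
        # candidate pixel offsets around each point's containing pixel
        reach = int(math.ceil(splat_radius / px)) + 1
        row0, col0 = grid.containing_pixel(x, y)
        r2 = splat_radius**2
        for dr in range(-reach, reach + 1):
            for dc in range(-reach, reach + 1):
                row, col = row0 + dr, col0 + dc
                ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
                if not np.any(ok):
                    continue
                cx, cy = grid.pixel_center(row[ok], col[ok])
                hit = (cx - x[ok]) ** 2 + (cy - y[ok]) ** 2 <= r2
                mask[row[ok][hit], col[ok][hit]] = True
    if close_gaps:
        mask = closing(mask, disk(closing_radius)).astype(bool)
    return VegetationMask(
        GeoRaster(grid, mask.astype(np.uint8), nodata=MASK_NODATA), splat_radius
    )


def apply_mask(ortho: GeoRaster, mask: VegetationMask) -> GeoRaster:
    """Blank every orthoimage pixel not supported by vegetation.

    Retained pixels keep their exact RGB values; removed pixels become
    nodata (validity mask false).
    """
    if not ortho.grid.same_grid(mask.grid):
        raise ValueError("orthoimage and vegetation mask are on different grids")
    keep = mask.as_bool() & ortho.valid_mask()
    if ortho.is_rgb:
        data = ortho.data.copy()
        data[~keep] = 0
        return GeoRaster(ortho.grid, data, valid=keep)
    data = ortho.data.copy()
    nodata = ortho.nodata if ortho.nodata is not None else MASK_NODATA
    data[~keep] = nodata
    return GeoRaster(ortho.grid, data, nodata=nodata)
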