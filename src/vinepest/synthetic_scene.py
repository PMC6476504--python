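"""Synthetic trellised-vineyard scenes: co-registered point cloud, RGB
orthoimage and truth masks with known canopy cover and pest impact.

The generator emulates the statistical structure the pipeline assumes,
at desk scale and fully seeded:

* gently undulating bare soil (smooth low-frequency relief) carrying
  brown radiometry;
* parallel trellised vine rows whose canopy curtain is lofted well
  above the ground (default 1.8 m tall, foliage concentrated in the
  upper wire zone);
* contiguous patches of affected (desiccated, brown) canopy whose
  color distribution overlaps the soil's — the confusion mode the
  method exists to resolve;
* optional shadow strips of darkened soil along row edges;
* a photogrammetry-like point cloud sampling both surfaces, with truth
  class per point, plus a handful of low-noise outliers.

Everything is drawn from one seeded generator, so identical parameters
give bit-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from shapely.geometry import Polygon

from .grids import GeoRaster, GridSpec
from .geomatic_io import (
    MASK_NODATA,
    PolygonSet,
    write_point_cloud,
    write_polygons,
    write_raster,
)
from .pointcloud import (
    CLASS_GROUND,
    CLASS_MEDIUM_VEGETATION,
    CLASS_NOISE,
    PointCloud,
)

__all__ = ["ColorModel", "SceneParams", "SyntheticScene", "generate_scene",
           "scene_to_fixtures", "suggest_patch"]


@dataclass(frozen=True)
class ColorModel:
    """Truncated-Gaussian RGB model per scene class.

    Soil is heterogeneous: a base brown-gray plus contiguous
    "confusable" patches (moist or clay-rich ground) whose color equals
    the affected-leaf color — the parts of the soil a purely
    radiometric classifier cannot tell from desiccated canopy.
    ``confusable_soil_fraction`` (share of soil area) is the difficulty
    knob of that mechanism; ``soil_affected_overlap`` additionally
    pulls the affected mean toward the base soil (0 = nominal colors,
    1 = identical)."""

    healthy: tuple[float, float, float] = (60.0, 110.0, 50.0)
    affected: tuple[float, float, float] = (130.0, 80.0, 45.0)
    soil: tuple[float, float, float] = (140.0, 110.0, 80.0)
    shadow_factor: float = 0.45  # shadow = darkened soil
    sigma: float = 8.0
    confusable_soil_fraction: float = 0.07
    soil_affected_overlap: float = 0.0

    def affected_mean(self) -> np.ndarray:
        a = np.asarray(self.affected, dtype=float)
        s = np.asarray(self.soil, dtype=float)
        t = self.soil_affected_overlap
        return a + t * (s - a)

    def confusable_soil_mean(self) -> np.ndarray:
        return self.affected_mean()

    def shadow_mean(self) -> np.ndarray:
        return np.asarray(self.soil, dtype=float) * self.shadow_factor


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry, sampling and radiometry.

    Defaults reproduce the conditions of the vineyard case: 0.015 m
    GSD, ~1,536 points m⁻², 1.8 m canopy on rows 3 m apart, ~14.2%
    canopy cover with ~9% of the canopy affected.
    """

    extent: tuple[float, float] = (50.0, 50.0)
    gsd: float = 0.015
    point_density: float = 1536.0
    terrain_amplitude: float = 0.5
    terrain_wavelength: float = 100.0
    row_spacing: float = 3.0
    row_width: float | None = None  # derived from canopy_cover_target if None
    canopy_height: float = 1.8
    canopy_cover_target: float = 0.142
    affected_fraction_of_canopy: float = 0.09
    shadow_width: float = 0.3
    ground_z_sigma: float = 0.005
    noise_rate: float = 0.0002
    colors: ColorModel = field(default_factory=ColorModel)
    origin: tuple[float, float] = (0.0, 0.0)
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.affected_fraction_of_canopy <= 1:
            raise ValueError("affected_fraction_of_canopy must be in [0, 1]")
        if not 0 < self.canopy_cover_target < 1:
            raise ValueError("canopy_cover_target must be in (0, 1)")
        if self.point_density <= 0 or self.gsd <= 0:
            raise ValueError("point_density and gsd must be > 0")

    def resolved_row_width(self) -> float:
        if self.row_width is not None:
            return self.row_width
        width = self.canopy_cover_target * self.row_spacing
        if width >= self.row_spacing:
            raise ValueError(
                "canopy_cover_target incompatible with row geometry: "
                f"attainable cover < {1.0:.2f} requires target < "
                f"{self.row_spacing / self.row_spacing:.2f}"
            )
        return width


@dataclass
class SyntheticScene:
    """Generated scene plus its realized (truth) statistics."""

    params: SceneParams
    cloud: PointCloud  # classification = truth class per point
    ortho: GeoRaster
    truth_veg_mask: GeoRaster
    truth_affected_mask: GeoRaster
    canopy_cover_pct: float
    affected_fraction_of_canopy_pct: float
    affected_area_pct: float

    @property
    def grid(self) -> GridSpec:
        return self.ortho.grid


def _terrain(x, y, params: SceneParams, phases) -> np.ndarray:
    """Smooth undulation: sum of two low-frequency sinusoids with
    seeded phases; peak-to-peak ≈ 2×amplitude over a wavelength."""
    lam = params.terrain_wavelength
    a = params.terrain_amplitude / 2.0
    return a * (
        np.sin(2 * np.pi * x / lam + phases[0])
        + np.cos(2 * np.pi * y / lam + phases[1])
    )


def _canopy_strips(x: np.ndarray, params: SceneParams) -> np.ndarray:
    """True where map-x falls inside a vine-row canopy strip."""
    width = params.resolved_row_width()
    offset = params.row_spacing / 2.0
    phase = np.mod(x - params.origin[0] - offset, params.row_spacing)
    return np.abs(phase - params.row_spacing / 2.0) >= (
        params.row_spacing - width
    ) / 2.0


def _shadow_strips(x: np.ndarray, params: SceneParams) -> np.ndarray:
    """Shadow band on the east side of each row (darkened soil)."""
    if params.shadow_width <= 0:
        return np.zeros_like(x, dtype=bool)
    width = params.resolved_row_width()
    offset = params.row_spacing / 2.0
    east_edge = offset + width / 2.0
    phase = np.mod(x - params.origin[0] - east_edge, params.row_spacing)
    return phase < params.shadow_width


def generate_scene(params: SceneParams | None = None) -> SyntheticScene:
    """Build the scene deterministically from ``params.seed``."""
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    ox, oy = params.origin
    width_m, height_m = params.extent
    n_cols = int(round(width_m / params.gsd))
    n_rows = int(round(height_m / params.gsd))
    grid = GridSpec(
        origin_x=ox,
        origin_y=oy + n_rows * params.gsd,  # origin param is the SW corner
        pixel_size=params.gsd,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_id="synthetic-metric",
    )
    xs, ys = grid.center_coords()

    veg_mask = np.broadcast_to(_canopy_strips(xs, params), grid.shape).copy()
    shadow_mask = (
        np.broadcast_to(_shadow_strips(xs, params), grid.shape) & ~veg_mask
    )

    # contiguous affected blobs: smooth random field thresholded at the
    # canopy quantile that realizes the target fraction
    affected = np.zeros(grid.shape, dtype=bool)
    if params.affected_fraction_of_canopy > 0:
        coarse_res = 0.5  # m
        cshape = (
            max(8, int(round(height_m / coarse_res))),
            max(8, int(round(width_m / coarse_res))),
        )
        fld = gaussian_filter(rng.standard_normal(cshape), sigma=3.0)
        fld = zoom(fld, (n_rows / cshape[0], n_cols / cshape[1]), order=1)
        fld = fld[:n_rows, :n_cols]
        canopy_vals = fld[veg_mask]
        thr = np.quantile(canopy_vals, 1.0 - params.affected_fraction_of_canopy)
        affected = veg_mask & (fld >= thr)

    n_canopy = int(veg_mask.sum())
    canopy_cover_pct = 100.0 * n_canopy / veg_mask.size
    affected_fraction_pct = (
        100.0 * affected.sum() / n_canopy if n_canopy else 0.0
    )
    affected_area_pct = 100.0 * affected.sum() / veg_mask.size

    # point cloud first (geometry is independent of the radiometric
    # settings): uniform XY, terrain z; canopy lofted to the upper wire
    # zone (0.6-1.0 x canopy height, a trellis foliage curtain)
    n_points = int(round(params.point_density * width_m * height_m))
    px = rng.uniform(ox, ox + width_m, size=n_points)
    py = rng.uniform(oy, oy + height_m, size=n_points)
    pz = _terrain(px, py, params, phases) + rng.normal(
        0.0, params.ground_z_sigma, size=n_points
    )
    in_canopy = _canopy_strips(px, params)
    loft = rng.uniform(0.6, 1.0, size=n_points) * params.canopy_height
    pz = np.where(in_canopy, pz + loft, pz)
    truth_class = np.where(
        in_canopy, CLASS_MEDIUM_VEGETATION, CLASS_GROUND
    ).astype(np.uint8)

    n_noise = int(round(params.noise_rate * n_points))
    if n_noise:
        nx = rng.uniform(ox, ox + width_m, size=n_noise)
        ny = rng.uniform(oy, oy + height_m, size=n_noise)
        nz = _terrain(nx, ny, params, phases) - rng.uniform(1.0, 3.0, size=n_noise)
        px = np.concatenate([px, nx])
        py = np.concatenate([py, ny])
        pz = np.concatenate([pz, nz])
        truth_class = np.concatenate(
            [truth_class, np.full(n_noise, CLASS_NOISE, dtype=np.uint8)]
        )

    # radiometry: heterogeneous soil (base + confusable dark patches
    # colored like desiccated leaves), shadows, canopy classes
    colors = params.colors
    soil_mask = ~veg_mask
    confusable = np.zeros(grid.shape, dtype=bool)
    if colors.confusable_soil_fraction > 0 and soil_mask.any():
        coarse_res = 0.5
        cshape = (
            max(8, int(round(height_m / coarse_res))),
            max(8, int(round(width_m / coarse_res))),
        )
        fld = gaussian_filter(rng.standard_normal(cshape), sigma=4.0)
        fld = zoom(fld, (n_rows / cshape[0], n_cols / cshape[1]), order=1)
        fld = fld[:n_rows, :n_cols]
        thr = np.quantile(
            fld[soil_mask], 1.0 - colors.confusable_soil_fraction
        )
        confusable = soil_mask & (fld >= thr)

    rgb = np.empty(grid.shape + (3,), dtype=np.float64)
    rgb[:] = np.asarray(colors.soil, dtype=float)
    rgb[confusable] = colors.confusable_soil_mean()
    rgb[shadow_mask & ~confusable] = colors.shadow_mean()
    rgb[veg_mask] = np.asarray(colors.healthy, dtype=float)
    rgb[affected] = colors.affected_mean()
    rgb += rng.normal(0.0, colors.sigma, size=rgb.shape)
    ortho = GeoRaster(grid, np.clip(np.round(rgb), 0, 255).astype(np.uint8))

    # per-point color sampled from the orthoimage class model
    row, col = grid.containing_pixel(px, py)
    row = np.clip(row, 0, n_rows - 1)
    col = np.clip(col, 0, n_cols - 1)
    point_rgb = ortho.data[row, col]

    cloud = PointCloud(
        np.column_stack([px, py, pz]), rgb=point_rgb, classification=truth_class
    )
    nodata = MASK_NODATA
    return SyntheticScene(
        params=params,
        cloud=cloud,
        ortho=ortho,
        truth_veg_mask=GeoRaster(grid, veg_mask.astype(np.uint8), nodata=nodata),
        truth_affected_mask=GeoRaster(grid, affected.astype(np.uint8), nodata=nodata),
        canopy_cover_pct=canopy_cover_pct,
        affected_fraction_of_canopy_pct=affected_fraction_pct,
        affected_area_pct=affected_area_pct,
    )


def mask_to_polygons(mask: GeoRaster, simplify_tol: float = 0.0) -> PolygonSet:
    """Vectorize a binary mask into map-coordinate polygons (marching
    squares on the pixel-center lattice)."""
    from skimage import measure

    grid = mask.grid
    padded = np.pad((mask.data == 1).astype(float), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        rr = contour[:, 0] - 1.0
        cc = contour[:, 1] - 1.0
        x = grid.origin_x + (cc + 0.5) * grid.pixel_size
        y = grid.origin_y - (rr + 0.5) * grid.pixel_size
        if len(x) < 4:
            continue
        poly = Polygon(np.column_stack([x, y]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area == 0:
            continue
        if simplify_tol > 0:
            poly = poly.simplify(simplify_tol)
        if poly.geom_type == "Polygon":
            polys.append(poly)
        else:  # MultiPolygon after repair
            polys.extend(g for g in poly.geoms if g.area > 0)
    return PolygonSet(polys, label="affected") if polys else PolygonSet([], label="affected")


def scene_to_fixtures(scene: SyntheticScene, out_dir: str | Path) -> dict:
    """Write the scene as standard files (LAS, GeoTIFF, GeoJSON) plus a
    manifest of the realized truth statistics; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_point_cloud(scene.cloud, out / "cloud.las")
    write_raster(scene.ortho, out / "ortho.tif")
    write_raster(scene.truth_veg_mask, out / "truth_veg_mask.tif")
    write_raster(scene.truth_affected_mask, out / "truth_affected_mask.tif")
    polys = mask_to_polygons(scene.truth_affected_mask)
    if len(polys):
        write_polygons(polys, out / "truth_affected.geojson")
    manifest = {
        "n_points": len(scene.cloud),
        "point_class_counts": {
            str(c): n for c, n in scene.cloud.class_counts().items()
        },
        "grid": {
            "origin_x": scene.grid.origin_x,
            "origin_y": scene.grid.origin_y,
            "pixel_size": scene.grid.pixel_size,
            "n_rows": scene.grid.n_rows,
            "n_cols": scene.grid.n_cols,
        },
        "canopy_cover_pct": scene.canopy_cover_pct,
        "affected_fraction_of_canopy_pct": scene.affected_fraction_of_canopy_pct,
        "affected_area_pct": scene.affected_area_pct,
        "truth_veg_pixels": int((scene.truth_veg_mask.data == 1).sum()),
        "truth_affected_pixels": int((scene.truth_affected_mask.data == 1).sum()),
        "seed": scene.params.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def suggest_patch(
    scene: SyntheticScene, size: int = 300, step: int | None = None
) -> tuple[int, int, int, int]:
    """Pick a training window (row0, col0, row1, col1) the way an
    operator would: centered on a clearly affected area, with healthy
    canopy and soil also present for the negative classes.

    Among windows where healthy canopy and soil each cover at least 5%
    of the pixels, the one with the most affected pixels wins — a small
    affected population cannot anchor its own chroma cluster, so the
    window is chosen to make it prominent.  Deterministic.
    """
    step = step or max(1, size // 4)
    veg = scene.truth_veg_mask.data == 1
    aff = scene.truth_affected_mask.data == 1
    healthy = veg & ~aff
    soil = ~veg
    n_rows, n_cols = scene.grid.shape
    best, best_score = None, -1.0
    fallback, fallback_score = None, -1.0
    for r0 in range(0, max(1, n_rows - size + 1), step):
        for c0 in range(0, max(1, n_cols - size + 1), step):
            sl = (slice(r0, r0 + size), slice(c0, c0 + size))
            n_aff = int(aff[sl].sum())
            n_healthy = int(healthy[sl].sum())
            n_soil = int(soil[sl].sum())
            window = (r0, c0, min(r0 + size, n_rows), min(c0 + size, n_cols))
            area = (window[2] - r0) * (window[3] - c0)
            if n_healthy >= 0.05 * area and n_soil >= 0.05 * area:
                if n_aff > best_score:
                    best_score = n_aff
                    best = window
            score = min(n_aff, n_healthy / 4.0, n_soil / 4.0)
            if score > fallback_score:
                fallback_score = score
                fallback = window
    if best is not None and best_score > 0:
        return best
    if fallback is not None and fallback_score > 0:
        return fallback
    raise ValueError("no window contains all three classes; enlarge the scene")
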