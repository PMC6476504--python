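"""End-to-end orchestration of the two analysis arms.

Arm A (radiometric only) trains and applies the pixel classifier on the
full orthoimage.  Arm B (geometric + radiometric) first splits the
point cloud into ground and vegetation, masks the orthoimage down to
vegetation-supported pixels, and trains/applies the classifier there.
Both arms are validated against the same truth mask over the same
validation mesh and aggregated onto the same impact grid, so their
comparison (ΔOA, ΔSPA, ΔSPN, false-positive reduction) isolates the
effect of the geometric step.

For validation and mapping, pixels outside the vegetation mask in arm
B count as *unaffected* (the vegetation-filtered affection binary
covers the whole plot with zeros off-canopy), which keeps the
considered-pixel population identical between arms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import GeoRaster
from .geomatic_io import MASK_NODATA, write_point_cloud, write_raster
from .ground_filter import GroundFilterParams, classify_ground
from .impact_map import grid_aggregate, plot_summary
from .laic import (
    AnnConfig,
    classify_raster,
    cluster_ab,
    label_clusters_by_reference,
    make_training_set,
    rgb_to_lab,
    train_ann,
)
from .pointcloud import PointCloud
from .synthetic_scene import SyntheticScene, suggest_patch
from .validation import (
    accuracy_metrics,
    confusion_matrix,
    make_validation_mesh,
    round_half_up,
)
from .vegetation_raster import apply_mask, points_to_mask

__all__ = ["PipelineConfig", "run_all", "config_for_scene"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved knobs of a full run; seeds are recorded in the report."""

    ground: GroundFilterParams = field(default_factory=GroundFilterParams)
    splat_radius: float = 0.0  # stamp the containing pixel only
    closing: bool = True
    closing_radius: int = 2  # bridge point-density gaps, no fringe growth
    patch: tuple[int, int, int, int] | None = None  # auto-picked if None
    patch_size: int = 300
    k_full: int = 5  # healthy, affected, soil, confusable soil, shadow
    k_nonground: int = 3
    affected_reference_rgb: tuple[float, float, float] = (120.0, 90.0, 55.0)
    cluster_labeling: dict | None = None  # explicit {cluster: class} override
    ann: AnnConfig = field(default_factory=AnnConfig)
    mesh_cell: float = 10.0
    mesh_gap: float = 10.0
    impact_cell: float = 1.0
    seed: int = 0


def config_for_scene(scene: SyntheticScene, **overrides) -> PipelineConfig:
    """Config whose labelling reference color matches the scene's
    affected color model (the knowledge an operator has by eye)."""
    defaults = dict(
        affected_reference_rgb=tuple(scene.params.colors.affected_mean()),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def _train_and_classify(
    ortho: GeoRaster,
    patch: tuple[int, int, int, int],
    k: int,
    config: PipelineConfig,
    arm: str,
) -> tuple[GeoRaster, dict]:
    r0, c0, r1, c1 = patch
    patch_rgb = ortho.data[r0:r1, c0:c1]
    patch_raster = GeoRaster(
        _crop_grid(ortho.grid, patch), patch_rgb,
        valid=None if ortho.valid is None else ortho.valid[r0:r1, c0:c1],
    )
    lab = rgb_to_lab(patch_raster)
    model, assignment = cluster_ab(lab, k=k, seed=config.seed)
    valid_patch = patch_raster.valid_mask()
    if config.cluster_labeling is not None:
        labeling = {int(c): v for c, v in config.cluster_labeling.items()}
    else:
        labeling = label_clusters_by_reference(
            assignment[valid_patch],
            patch_rgb[valid_patch],
            k,
            config.affected_reference_rgb,
        )
    x, y = make_training_set(
        assignment[valid_patch], labeling, patch_rgb[valid_patch]
    )
    ann = AnnConfig(
        hidden_layers=config.ann.hidden_layers,
        activation=config.ann.activation,
        max_epochs=config.ann.max_epochs,
        learning_rate=config.ann.learning_rate,
        seed=config.seed,
        threshold=config.ann.threshold,
        max_train_samples=config.ann.max_train_samples,
    )
    clf = train_ann(x, y, ann)
    pred = classify_raster(ortho, clf)
    stage = {
        "arm": arm,
        "k": k,
        "cluster_labeling": {str(c): v for c, v in sorted(labeling.items())},
        "training_pixels": int(len(y)),
        "training_positives": int(y.sum()),
    }
    return pred, stage


def _crop_grid(grid, patch):
    from .grids import GridSpec

    r0, c0, r1, c1 = patch
    return GridSpec(
        origin_x=grid.origin_x + c0 * grid.pixel_size,
        origin_y=grid.origin_y - r0 * grid.pixel_size,
        pixel_size=grid.pixel_size,
        n_rows=r1 - r0,
        n_cols=c1 - c0,
        crs_id=grid.crs_id,
    )


def _zero_fill(pred: GeoRaster) -> GeoRaster:
    """Nodata pixels become 'unaffected' so both arms cover the plot."""
    data = np.where(pred.valid_mask(), pred.data, 0).astype(np.uint8)
    return GeoRaster(pred.grid, data, nodata=MASK_NODATA)


def run_all(
    ortho: GeoRaster,
    cloud: PointCloud,
    truth_affected: GeoRaster,
    config: PipelineConfig | None = None,
    truth_veg: GeoRaster | None = None,
    scene: SyntheticScene | None = None,
    classified_cloud: PointCloud | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run both arms, validate against truth, and return (and optionally
    write) the comparison report."""
    config = config or PipelineConfig()
    grid = ortho.grid
    report: dict = {"seed": config.seed, "stages": []}

    patch = config.patch
    if patch is None:
        if scene is None:
            raise ValueError("no training patch given and no scene to pick one from")
        patch = suggest_patch(scene, size=config.patch_size)
    report["patch"] = list(patch)

    # ---- arm A: classifier on the full orthoimage -----------------------
    pred_a, stage_a = _train_and_classify(ortho, patch, config.k_full, config, "full")
    pred_a = _zero_fill(pred_a)
    report["stages"].append(stage_a)

    # ---- arm B: ground filter -> vegetation orthoimage -> classifier ----
    if classified_cloud is not None:
        classified = classified_cloud
    else:
        bare = PointCloud(cloud.xyz, rgb=cloud.rgb)  # drop any prior classes
        classified = classify_ground(bare, config.ground)
    report["stages"].append(
        {"arm": "nonground", "point_class_counts": classified.class_counts()}
    )
    veg_mask = points_to_mask(
        classified,
        grid,
        config.splat_radius,
        close_gaps=config.closing,
        closing_radius=config.closing_radius,
    )
    veg_ortho = apply_mask(ortho, veg_mask)
    pred_b, stage_b = _train_and_classify(
        veg_ortho, patch, config.k_nonground, config, "nonground"
    )
    pred_b = _zero_fill(pred_b)
    report["stages"].append(stage_b)

    # ---- validation over the shared mesh --------------------------------
    from .geomatic_io import rasterize_polygons

    mesh = make_validation_mesh(grid, config.mesh_cell, config.mesh_gap)
    region = rasterize_polygons(mesh, grid)
    results = {}
    for arm, pred in (("full", pred_a), ("nonground", pred_b)):
        cm = confusion_matrix(pred, truth_affected, region)
        results[arm] = accuracy_metrics(cm).rounded()
    fp_a, fp_b = results["full"]["FP"], results["nonground"]["FP"]
    comparison = {
        "delta_OA": _delta(results, "OA"),
        "delta_SPA": _delta(results, "SPA"),
        "delta_SPN": _delta(results, "SPN"),
        "fp_full": fp_a,
        "fp_nonground": fp_b,
        "fp_reduction_pct": round_half_up(100.0 * (fp_a - fp_b) / fp_a)
        if fp_a > 0
        else None,
    }

    # ---- impact / canopy grids ------------------------------------------
    canopy_grid = grid_aggregate(veg_mask.raster, config.impact_cell)
    maps = {}
    for arm, pred in (("full", pred_a), ("nonground", pred_b)):
        impact = grid_aggregate(pred, config.impact_cell)
        maps[arm] = plot_summary(impact, canopy_grid)
    report.update(
        {
            "validation_mesh_cells": len(mesh),
            "validation": results,
            "comparison": comparison,
            "impact": maps,
        }
    )
    if scene is not None:
        report["truth"] = {
            "canopy_cover_pct": scene.canopy_cover_pct,
            "affected_fraction_of_canopy_pct": scene.affected_fraction_of_canopy_pct,
            "affected_area_pct": scene.affected_area_pct,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_point_cloud(classified, out / "classified.las")
        write_raster(veg_mask.raster, out / "veg_mask.tif")
        write_raster(pred_a, out / "affection_full.tif")
        write_raster(pred_b, out / "affection_nonground.tif")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _delta(results: dict, key: str):
    a, b = results["full"][key], results["nonground"][key]
    if a is None or b is None:
        return None
    return round_half_up(b - a, 2)
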