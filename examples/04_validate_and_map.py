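"""Validate a classification against truth and build 1 m2 impact maps.

Confusion matrix over a 10 m checkerboard mesh, overall accuracy and
per-class success percentages, then per-cell impact and canopy-cover
percentages and the plot summary.
"""

import json

import vinepest as vp

scene = vp.generate_scene(
    vp.SceneParams(extent=(20.0, 20.0), gsd=0.03, point_density=500.0, seed=5)
)
# classify with a quickly trained model (see example 03)
r0, c0, r1, c1 = vp.suggest_patch(scene, size=150)
patch_rgb = scene.ortho.data[r0:r1, c0:c1]
model, assignment = vp.cluster_ab(vp.rgb_to_lab(patch_rgb), k=4, seed=0)
labeling = vp.label_clusters_by_reference(
    assignment, patch_rgb, 4, tuple(scene.params.colors.affected_mean())
)
x, y = vp.make_training_set(assignment, labeling, patch_rgb)
pred = vp.classify_raster(scene.ortho, vp.train_ann(x, y, vp.AnnConfig(seed=0)))

mesh = vp.make_validation_mesh(scene.grid, cell_side=10.0, gap=10.0)
region = vp.rasterize_polygons(mesh, scene.grid)
cm = vp.confusion_matrix(pred, scene.truth_affected_mask, region)
report = vp.accuracy_metrics(cm).rounded()
print("validation over", len(mesh), "mesh cells:")
print(json.dumps(report, indent=2))
print("OA = overall accuracy; SPA/SPN = success % of the affected /"
      " unaffected class; commission = false positives over considered pixels")

impact = vp.grid_aggregate(pred, cell_size=1.0)
canopy = vp.grid_aggregate(scene.truth_veg_mask, cell_size=1.0)
summary = vp.plot_summary(impact, canopy)
print(f"\nplot affected area: {summary['affected_area_pct']:.2f} % | "
      f"canopy cover: {summary['canopy_cover_pct']:.2f} % | "
      f"affected fraction of canopy: "
      f"{summary['affected_fraction_of_canopy_pct']:.1f} %")
grades = vp.grade_map(impact)
print("impact grade histogram (grades 1-4):",
      [int((grades.data == g).sum()) for g in (1, 2, 3, 4)])
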