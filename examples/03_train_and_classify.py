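"""Train the affected-pixel classifier and apply it to the orthoimage.

A training window is clustered in CIE-Lab chroma; clusters are related
to {affected, other} by their mean color; the labelled pixels train a
small RGB-input neural network that then scores every pixel.
"""

import numpy as np

import vinepest as vp

scene = vp.generate_scene(
    vp.SceneParams(extent=(20.0, 20.0), gsd=0.03, point_density=500.0, seed=5)
)
r0, c0, r1, c1 = vp.suggest_patch(scene, size=150)
patch_rgb = scene.ortho.data[r0:r1, c0:c1]

lab = vp.rgb_to_lab(patch_rgb)
model, assignment = vp.cluster_ab(lab, k=4, seed=0)
labeling = vp.label_clusters_by_reference(
    assignment, patch_rgb, 4,
    affected_rgb=tuple(scene.params.colors.affected_mean()),
)
print("cluster labelling:", labeling)

x, y = vp.make_training_set(assignment, labeling, patch_rgb)
clf = vp.train_ann(x, y, vp.AnnConfig(seed=0))
pred = vp.classify_raster(scene.ortho, clf)

veg = scene.truth_veg_mask.data == 1
truth = scene.truth_affected_mask.data[veg] == 1
agreement = (pred.data[veg] == truth).mean()
print(f"training pixels: {len(y):,} ({int(y.sum()):,} affected)")
print(f"agreement with truth over vegetation pixels: {100 * agreement:.2f} %")
print(f"pixels classified affected (whole scene): "
      f"{int((pred.data == 1).sum()):,} — includes soil false positives; "
      "the next example removes them with the vegetation mask")
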