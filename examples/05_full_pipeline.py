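"""Run both analysis arms end to end and compare them.

Arm A classifies the full orthoimage (radiometry only).  Arm B first
removes the ground — point-cloud filtering, vegetation mask — and
classifies only canopy pixels.  The comparison isolates how much of
arm A's detected 'damage' was soil confused with desiccated leaves.
"""

import json

import vinepest as vp

scene = vp.generate_scene(
    vp.SceneParams(extent=(20.0, 20.0), gsd=0.03, point_density=500.0, seed=5)
)
config = vp.config_for_scene(scene, seed=1, patch_size=150)
report = vp.run_all(
    scene.ortho,
    scene.cloud,
    scene.truth_affected_mask,
    config,
    truth_veg=scene.truth_veg_mask,
    scene=scene,
)

print("arm comparison:", json.dumps(report["comparison"], indent=2))
truth = report["truth"]["affected_fraction_of_canopy_pct"]
for arm in ("full", "nonground"):
    est = report["impact"][arm]["affected_fraction_of_canopy_pct"]
    print(f"{arm:>9} arm: affected fraction of canopy = {est:6.2f} % "
          f"(truth {truth:.2f} %)")
print("The radiometric-only arm overestimates by counting confusable "
      "soil; the geometric step removes those false positives.")
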