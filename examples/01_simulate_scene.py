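"""Generate a small synthetic vineyard scene and inspect its truth.

The scene couples a photogrammetry-like point cloud with an RGB
orthoimage and truth masks; printed numbers are the realized canopy
cover and pest impact the rest of the examples try to recover.
"""

import vinepest as vp

params = vp.SceneParams(extent=(20.0, 20.0), gsd=0.03, point_density=500.0, seed=5)
scene = vp.generate_scene(params)

print(f"orthoimage: {scene.grid.n_rows} x {scene.grid.n_cols} px "
      f"at {scene.grid.pixel_size} m GSD")
print(f"point cloud: {len(scene.cloud):,} points, "
      f"classes {scene.cloud.class_counts()}")
print(f"canopy cover:          {scene.canopy_cover_pct:.2f} %  "
      "(share of ground area under vine canopy)")
print(f"affected canopy share: {scene.affected_fraction_of_canopy_pct:.2f} %  "
      "(share of the canopy hit by the pest)")
print(f"affected area:         {scene.affected_area_pct:.2f} %  "
      "(share of the whole plot)")
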