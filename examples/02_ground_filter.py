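"""Separate ground from vine canopy in the dense point cloud.

Progressive TIN densification: per-cell lowest points seed a terrain
triangulation, then points within 1 m and 15 degrees of the growing
surface are accepted as ground.  Canopy on a 1.8 m trellis fails both
tests and remains vegetation.
"""

import vinepest as vp

scene = vp.generate_scene(
    vp.SceneParams(extent=(20.0, 20.0), gsd=0.03, point_density=500.0, seed=5)
)
bare = vp.PointCloud(scene.cloud.xyz)  # classification withheld
params = vp.GroundFilterParams(cell_size=6.0, max_angle=15.0, max_distance=1.0)
classified = vp.classify_ground(bare, params)

counts = classified.class_counts()
print(f"ground (2): {counts.get(2, 0):,}   vegetation (4): "
      f"{counts.get(4, 0):,}   noise (7): {counts.get(7, 0):,}")

truth = scene.cloud.classification
pred = classified.classification
g = truth == vp.CLASS_GROUND
c = truth == vp.CLASS_MEDIUM_VEGETATION
print(f"ground recovery:  {100 * (pred[g] == vp.CLASS_GROUND).mean():.2f} % "
      "of true ground points recovered")
print(f"canopy recovery:  {100 * (pred[c] == vp.CLASS_MEDIUM_VEGETATION).mean():.2f} % "
      "of true canopy points recovered")
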