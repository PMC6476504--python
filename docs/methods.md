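# Methods

`vinepest` quantifies leafhopper (*Jacobiasca lybica*) damage on
trellised vineyards from two UAV photogrammetry products: a dense RGB
point cloud and a co-registered RGB orthoimage.  The package combines a
geometric step (terrain/canopy separation in 3D) with a radiometric
step (per-pixel color classification), because the two failure modes
are complementary: desiccated leaves are radiometrically close to parts
of the bare soil, but they sit ~1.8 m above it on the trellis.

## Ground filtering (progressive TIN densification)

The cloud is split into ground and vegetation with a two-step adaptive
TIN procedure in the style of Axelsson's filter:

1. **Seeding.**  The cloud is partitioned into square cells of
   `cell_size` (default 6 m, matched to the plot's rugosity and row
   spacing); the lowest point of each non-empty cell seeds a 2D
   Delaunay triangulation — the first terrain approximation.  Before
   seeding, low outliers (points more than `noise_sigma` = 5 robust
   standard deviations below their cell's median height, with a 2 cm
   floor on the robust scale) are tagged as noise (LAS class 7) so
   they cannot drag the terrain model down.
2. **Densification.**  Iteratively, every unclassified point is tested
   against the facet containing its horizontal position: it becomes
   ground when its plumb-line distance to the facet plane is at most
   `max_distance` (default 1 m) *and* the largest angle between the
   facet plane and the segments from the facet's three vertices to the
   point is at most `max_angle` (default 15°).  All acceptances of an
   iteration are applied together and the TIN is rebuilt once, so the
   result does not depend on point order.  The process stops when an
   iteration accepts nothing (or at `max_iterations` = 50).

Points left unaccepted are labelled medium vegetation (LAS class 4);
ground is class 2.  Points below the TIN are treated symmetrically
(|distance|), so depressions are not carved out of the terrain.
Points outside the TIN's convex hull are evaluated against a facet of
the nearest vertex and flagged as extrapolated.

**Distance metric.**  The distance is the *vertical* (plumb-line)
offset between the point and the facet plane at the point's own XY,
not the perpendicular distance.  On near-horizontal terrain facets the
two are identical, and all closed-form identities (a point at height
*h* above a horizontal facet has distance *h* and angle `atan(h/r)` to
a vertex at horizontal range *r*) are unchanged.  The difference
matters at photogrammetric density (~2.5 cm point spacing): facets
between height-jittered vertices can be locally steep, and a
perpendicular rule accepts points *sideways* along such facets, letting
the terrain model climb a canopy curtain once any elevated point slips
in.  The plumb-line rule bounds the comparison by local micro-relief,
which keeps a 1.8 m canopy unreachable from ground planes under the
1 m / 15° defaults.

**Scaling.**  A naive implementation re-triangulates millions of
points every iteration.  The implementation splits the run into a bulk
phase (large acceptance batches; full re-triangulation and full
re-evaluation) and a tail phase for small batches: by the Delaunay
empty-circumcircle property, inserting a few vertices only changes
facets inside the cavity around them, so previously rejected points
farther away keep their metrics and stay rejected.  The tail therefore
re-triangulates only a neighbourhood of ~20 typical point spacings
around the freshly accepted points and re-tests only candidates within
the changed radius (the longest edge of the facets touching the new
vertices; facets longer than half the selection radius are cut
artifacts of the local selection and are excluded from that bound).
On the reference scene (3.8 M points) this runs in ~5 minutes on one
CPU; results are identical to the naive loop on desk-scale scenes.

## Vegetation orthoimage

The original workflow rendered a second orthomosaic from vegetation
points only.  Here the existing orthoimage is masked instead: a pixel
is kept iff at least one vegetation-classified point falls within
`splat_radius` of its center (radius 0 keeps only each point's
containing pixel), optionally followed by one binary closing pass
(disk of `closing_radius` px) to bridge gaps where point density
undershoots pixel density (1,536 pts/m² against 1.5 cm pixels leaves
~45% of canopy pixels without a point of their own).  The pipeline
default is radius 0 with a disk-2 closing: closing fills interior
holes (<1% remain at the reference density) but, unlike a larger splat
radius, never pushes the mask boundary beyond the outermost vegetation
points, keeping the soil fringe inside the mask to ≤1 px.  That fringe
matters because fringe pixels of confusable soil are color-identical
to affected leaves — a 2×GSD splat adds a ~3 px fringe and inflates
the masked arm's affected estimate by ~80% on the reference scene.
Radiometry of kept pixels is bit-identical to the input, which is all
a per-pixel classifier consumes; orthomosaic re-rendering is out of
scope.  The tight mask slightly *undercovers* the true canopy
footprint (boundary pixels without points recede), biasing measured
canopy cover down ~2 points and the affected-fraction ratio slightly
up.

## Affected-pixel classification

The classifier follows the cluster-assisted supervised recipe of
leaf-area mapping tools for very-high-resolution RGB imagery:

1. a small training window of the orthoimage is converted from sRGB
   (D65) to CIE 1976 L*a*b*;
2. k-means (k ∈ [2, 10], k-means++ init, 10 restarts, tolerance 1e-6,
   fixed seed) runs on the chromatic (a*, b*) components only —
   lightness is excluded so shadows do not dominate the partition;
3. each cluster is related to {affected, other}.  In the original tool
   this is an interactive step; here it is config-driven: either an
   explicit mapping, or an automatic rule that labels the cluster(s)
   whose mean RGB lies within 25 units of a declared affected
   reference color (the nearest cluster is always labelled).  The
   automatic rule emulates the operator's visual judgement and never
   consults truth masks;
4. the labelled pixels train a multilayer perceptron on *RGB* inputs
   (one hidden layer of 10 logistic units, single sigmoid output,
   cross-entropy loss via L-BFGS full-batch optimization, inputs
   scaled to [0, 1], fixed seed).  Training sets larger than 20,000
   pixels are subsampled with class stratification — color
   distributions are three-dimensional and saturate far below that;
5. the trained network scores every valid pixel; scores ≥ 0.5 become
   affected (1), others 0, nodata propagates.

The network architecture, threshold and subsampling cap are all
exposed in `AnnConfig`.

## Validation

Truth polygons are rasterized onto the prediction grid with the
pixel-center rule (a pixel counts as affected iff its center is inside
a polygon).  The validation region is a checkerboard mesh of 10 m
squares separated by 10 m gaps, aligned to the raster origin.  Over
the considered pixels (mesh ∩ valid data in both rasters) the package
counts TP/FP/FN/TN and reports

    OA  = 100 (TP + TN) / total
    SPA = 100 TP / (TP + FN)
    SPN = 100 TN / (TN + FP)

plus commission (FP) and omission (FN) rates, overall and per mesh
cell; per-cell errors are emitted under both normalizations (per-cell
pixels and total considered pixels) because either convention is
defensible.  SPA/SPN are reported as not-applicable — never 0 — when
their class is absent.  Report tables round half-up to one decimal.
For the vegetation-masked arm, pixels outside the mask count as
*unaffected* rather than nodata, so both arms are validated over the
same pixel population.

## Impact and canopy-cover maps

The binary affection raster is aggregated onto 1 m² cells anchored at
the raster origin: cell value = 100 × mean of its considered binary
pixels; edge cells keep their partial pixel counts and are flagged by
those counts rather than dropped.  The same operator applied to the
vegetation mask gives canopy cover.  Plot-level percentages are
pixel-weighted means of the cells (which makes them exactly equal to
the global binary mean), and

    affected fraction of canopy = 100 × affected% / canopy%.

A thematic grade map assigns four grades with half-open intervals at
the default breaks [25, 50, 75) — the number of grades matches the
published maps; the break values are a package choice and are
configurable.

## Synthetic vineyard scenes

No field data are deposited, so every stage is exercised on generated
scenes with known truth.  The generator emulates the case-study
structure at desk scale; defaults are the study conditions: 50 m ×
50 m, GSD 0.015 m, 1,536 points/m², rows 3 m apart, 1.8 m canopy,
14.2% canopy cover target, 9% of the canopy affected, seed 42.

* **Terrain** is a sum of two low-frequency sinusoids (amplitude
  0.5 m over a 100 m wavelength, seeded phases) — enough relief to
  exercise the TIN without challenging the 15°/1 m defaults, matching
  the gentle rugosity of a worked vineyard plot.
* **Rows** are parallel north–south canopy strips; strip width is
  derived from the canopy-cover target (cover × spacing ≈ 0.43 m for
  the defaults).  Canopy points are lofted uniformly over
  [0.6, 1.0] × canopy height (≈1.1–1.8 m): a trellis curtain carries
  its foliage in the upper wire zone, and photogrammetric matching
  rarely reconstructs the thin trunk zone.  Ground points follow the
  terrain with 5 mm height jitter; a small fraction (2×10⁻⁴) of low
  outliers 1–3 m below the terrain emulates matching blunders.
* **Affected patches** are contiguous blobs: a smoothed Gaussian
  random field thresholded at the canopy quantile that realizes the
  target fraction exactly (to one pixel).
* **Radiometry** is truncated-Gaussian RGB per class (σ = 8 per
  channel): healthy canopy (60, 110, 50), desiccated/affected canopy
  (130, 80, 45) — a reddish brown, chosen so that it is separable
  from soil in the (a*, b*) chroma plane (distance ≈ 12, within-class
  chroma spread ≈ 6) the way an operator could separate it on real
  imagery — base soil (140, 110, 80), and shadow strips of darkened
  soil along row edges.  Soil is deliberately heterogeneous: a
  configurable fraction (default 7%) of the soil area forms contiguous
  "confusable" patches colored exactly like affected leaves (moist or
  clay-rich ground).  This reproduces the documented failure mode of
  purely radiometric classification — *some parts* of the soil are
  indistinguishable from desiccated canopy in RGB — while leaving the
  training patch clusterable.  `confusable_soil_fraction` and
  `soil_affected_overlap` (which pulls the affected mean toward base
  soil) are the difficulty knobs.
* Geometry is drawn before radiometry, so the point cloud is invariant
  to color-model settings; identical parameters and seed give
  bit-identical scenes.

What passing on these scenes does **not** show: robustness to mixed
boundary pixels (class colors switch abruptly at truth-mask edges),
orthomosaic seam and illumination gradients, within-canopy gaps and
understory vegetation, real soil texture, or georeferencing error.
The scenes test the *mechanism* — geometric removal of radiometric
soil confusion — not photogrammetric realism.

## Pipeline and reproducibility

`run_all` executes both arms on one scene — (A) classify the full
orthoimage; (B) ground-filter → vegetation mask → classify the masked
orthoimage — then validates both against the same rasterized truth on
the same mesh and reports ΔOA/ΔSPA/ΔSPN, false-positive counts and the
commission-error reduction, plus 1 m² impact and canopy grids and
plot summaries for both arms.  Every random stage (scene, k-means,
network initialization, training subsampling) takes an explicit seed
recorded in the report; identical configuration and seeds give
byte-identical JSON reports.

Problem sizes: unit tests run desk-top scenes (15–20 m, 3 cm GSD,
300–500 pts/m²; seconds per test); the acceptance tests and the
acceptance script run the reference 50 m scene (11.1 M pixels, 3.8 M
points), where ground filtering takes a few minutes and each
classification arm ~1 minute on one CPU.

## Known limitations

* The ground filter's tail-phase locality bound is exact for interior
  points but approximates the "nearest facet" rule for points outside
  the convex hull; at most a boundary-fringe of points is affected.
* Exact translation invariance of the filter is limited by floating
  point: shifting coordinates can flip cell- and triangle-boundary
  ties (measured ≲0.2% of labels on desk scenes).
* LAS support covers point formats 0–3 (the fields the method uses);
  compressed LAZ is not supported — use XYZ text or LAS 1.2–1.4.
* The classifier is a color model only; it inherits every limitation
  of RGB radiometry (no NIR, no texture, no height features beyond the
  mask itself).
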