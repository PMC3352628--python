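# Methods

This note records the models, conventions, numerical choices and known
limitations of the toolkit, in the order of the processing chain.

## Volume model and Hounsfield units

A volume is a structured grid of scalar HU samples in `(slice, row, column)`
order with anisotropic spacing `(dz, dy, dx)` in mm.  Conventions chosen
once and used everywhere:

* voxel indices are 0-based; a voxel's world coordinate is its **center**,
  `origin + (index + 0.5) · spacing`; the world extent of an axis is
  `n · spacing` (half-open voxel cells);
* slices are stacked in ascending z (axial stack); patient-orientation
  handling beyond that is out of scope;
* HU values are **clamped** (not rejected) to the 12-bit scanner range
  [−1024, 3071] on ingest.

`hu_from_attenuation` implements `HU = 1000·(ρ_μ/ρ_water − 1)`; the ratio
form makes the water (0 HU) and air (−1000 HU) anchors exact in floating
point.

I/O: DICOM series are read via pydicom (slices sorted by patient-z, rescale
slope/intercept applied; non-uniform slice steps — e.g. a missing slice —
raise `InconsistentSpacingError`).  NIfTI-1 read/write via nibabel.  The
`raw_json` fixture format (little-endian int16 block + JSON sidecar with
shape/spacing/origin) exists so tests and CLI round-trips never need DICOM;
all three round-trip 12-bit integer data losslessly.

## Phantoms

The phantom module generates the toolkit's entire test bed; no external data
is used.

**Cubic verification phantom** — a 120 mm water cube holding 2 mm spheres on
a regular lattice, scanned at 1 mm slice thickness into 120 slices of
512×512 pixels.  The lattice pitch is not fixed by the geometry description,
so 10 mm is the default (configurable).  Voxelization is by center
inclusion: a voxel is foreground when its center lies inside the analytic
surface — the simplest rule that is exactly testable (a 2 mm sphere sampled
at 0.25 mm voxels recovers (4/3)π r³ within 15 %).

**Thorax phantom** — an elliptic soft-tissue body (40 HU) on air (−1000 HU)
with two ellipsoidal lungs (−800 HU, each one 6-connected component) and a
cylindrical bone-valued spine (700 HU).  Tissue levels are physically
plausible and far apart so HU windows can be varied in tests.  The spine
radius (16 mm at the default field of view) keeps its cross-section above
the 6 cm² small-region cutoff.  Optional Gaussian HU noise (default off,
sd in HU) is drawn from the spec's seed; generation is a pure function of
the spec.  Ground-truth masks (`left_lung`, `right_lung`, `spine`, `body` =
soft tissue) are pairwise disjoint; `GroundTruth.skin_mask()` returns their
union — the region an outer-contour tracer delineates, and the reference
for "skin/body" recovery.

What the phantoms do **not** emulate: CT acquisition physics (beam
hardening, reconstruction artifacts, partial-volume blur), textured organs,
and anatomy touching the scan border.  Passing the recovery tests therefore
shows the algorithms are correct on well-separated, piecewise-constant
anatomy with additive Gaussian noise — not that the default windows work on
arbitrary patient scans.

## Filters

Convolution is true convolution (kernel flipped), reflect border by default
(zero-padding optional); the brute-force nested-loop oracle in the test
suite pins the semantics.  Smoothing is the K×K box mean.  Sobel magnitudes
are left unscaled (classic integer masks; a unit step yields interior
magnitude 4) since only relative magnitudes matter downstream.

Thresholding follows `I ≥ T → object (1)`: the formula convention wins over
any "white/black" prose description, because downstream the organ of
interest must be label 1.  `histogram_threshold` concretizes
"histogram-derived" as the interior minimum (valley) of the box-smoothed
histogram within an HU window, falling back to the window midpoint when no
interior valley exists.

## Segmentation

Per-slice pipeline (one user seed for the whole structure):

1. **HU-window threshold** `low ≤ I ≤ high` (Eq-5 rule applied two-sided).
2. **Majority filter** (box-smooth the binary labels, re-threshold at 0.5;
   default 3×3).  Smoothing the binary mask rather than the grey image is
   deliberate: box-smoothing HU values first blends air (−1000) and soft
   tissue (40) through *every* intermediate window, which turns the skin
   boundary into a spurious in-window ring for a lung window.
3. **Small-region removal**: 8-connected regions with area ≤ 6 cm²
   (default, configurable) are dropped — bright spots inside an organ are
   meaningless for delineation and would derail the trace.
4. **Seed resolution**: a seed on background is relocated by scanning rings
   of increasing radius (row-major within a ring) until the first object
   region is touched, then pulled strictly inside it (all 4-neighbours
   object) so tracing does not start on a ragged edge.
5. **Boundary tracing**: Moore 8-neighbour following with a clockwise scan
   starting from the backtrack (background) direction, i.e. keeping the
   region consistently on one side.  For a seed already on the object, the
   trace starts at the component's topmost-leftmost pixel, which is
   guaranteed to lie on the *outer* boundary (starting from an arbitrary
   interior probe can land on a hole boundary).  Termination is Jacob's
   criterion — stop on re-entering the start pixel from the start
   direction — with a repeated-state check as a safety net.  The traced
   pixel set equals the morphological boundary (object minus 4-erosion) on
   filled 4-connected components; the test suite asserts exact agreement on
   100 random blobs.
6. **Decimation** (optional, default off in the pipeline; `k` configurable)
   and conversion to mm contours.

Slice-to-slice propagation uses the filled region's centroid as the next
seed (relocation handles centroids that fall on background, e.g. concave
regions).  Tracking stops in a direction when the slice mask is empty or
the new region no longer overlaps the previous slice's region; the partial
result is returned with a warning record.  The returned mask is defined as
the per-slice polygon fill of the returned contours, so re-filling the
contours reproduces the mask exactly by construction.

**Region growing** accepts a voxel when its grey-level difference to an
adjacent already-accepted voxel is `≤ δ` (6-connected).  The inclusive
comparison makes `δ = 0` the exact-value connected component rather than a
degenerate single voxel.  The accepted set is the reachability closure of
the seed under steps of `|Δ| ≤ δ`, hence independent of visit order; the
implementation is a vectorized frontier BFS and is tested for exact
equality against a depth-first flood-fill oracle.  Comparison against the
seed value instead of the adjacent voxel is available as
`compare_to="seed"` (the growth criterion is stated ambiguously in the
literature; both readings are useful).

The default HU window is a parameter with no universal value: a constant
20–70 HU window (a soft-tissue band) cannot capture air-filled lungs at
−800 HU, so the thorax tests use windows appropriate to each tissue
(lungs −950..−600, spine 300..1200, body −500..3071).

## Contours

Area is the absolute shoelace sum (mm² → cm²); periphery the polyline
length including the closing segment (mm → cm); both in mm space.
Decimation keeps `m = ⌊N(1−k/100)⌋` points by uniform stride (indices
`⌊i·N/m⌋`), always retaining the first point; uniform stride (rather than
curvature-aware simplification) is enough to preserve the general shape —
a 512-point circle changes area and periphery by < 2 % at k = 20 %.  The
default removal fraction k = 20 % is the value at which the floor rule
reproduces the decimated point counts 530→424, 712→569 and 418→334.

Inter-slice interpolation winds both contours counter-clockwise, resamples
each into `sectors` (default 64) equiangular rays about its own area
centroid (taking the farthest ray–polygon intersection), and blends matched
sector points linearly — equivalent to intersecting the sides of the
triangles joining corresponding sector points with the intermediate plane.
Requirements and edge handling: contours must be closed with non-zero area
and star-shaped about their centroid (otherwise `DegenerateContourError`);
`t = 0/1` reproduce the resampled inputs to 1e−9 mm; output is independent
of the input winding direction.  Branching structures (one contour becoming
two) are out of scope.

Rasterization (`contours_to_mask`) is per-slice even-odd scanline fill of
pixel centers, OR-ed with the drawn outline between consecutive points —
the same convention the segmenter uses, which is what makes the
mask → trace → fill round trip exact.

## Resampling

`lerp`, `bilerp`, `trilerp` are the standard linear family; the trilinear
weights are the per-axis products of (coordinate or 1−coordinate), which
sum to 1 (convex combination) and reduce to the bilinear form on each face.
A published variant of the trilinear formula that assigns two weights to
one corner and none to another is a typo and is not reproduced.
Extrapolation (coordinates outside [0, 1]) is refused.

`resample_to_isotropic` keeps the world extent, samples
`round(extent/target)` voxel centers per axis through the trilinear
interpolator, and edge-clamps positions within half a voxel of the border.
Linear ramps are reproduced exactly at interior samples; a target spacing
coarser than twice the volume extent is rejected as degenerate.

## Rendering

All renderers march rays from an image plane placed one volume-diagonal in
front of the volume center (parallel mode) or fanned from a source point
(perspective / beam's-eye-view mode).  Samples are trilinear; the last
partial step of each ray is weighted by its true width so homogeneous-slab
integrals are exact.

* **DRR**: Riemann sum of `K(sample)·step`, `I = I₀·exp(−Σ)`.  A
  homogeneous slab matches Beer–Lambert within 0.5 % at step D/100 (and to
  machine precision for rays normal to the slab).  The depth buffer stays
  at the far plane — transparent mode has no surface.
* **Semi-transparent**: front-to-back `I = Σ C α T`, `T = Π(1−α)`, opacity
  per sample (not rescaled by step), early termination at `T < 1e−3`,
  Z-buffer set where accumulated opacity first crosses 0.5.  Front-to-back
  with early termination was chosen over back-to-front for the usual
  performance reason; the accumulated result is identical.
* **Isosurface**: first sign change of `sample − isovalue`, one linear
  sub-step refinement, Lambertian shading `|g·L|` with the
  central-difference gradient (step = half the smallest voxel spacing) and
  a headlight by default.

Depth increases away from the viewer.  Polygon compositing scan-converts
each beam/block polygon to per-pixel depth `Z_P` (affine interpolation of
the projected plane — exact for parallel projection, an approximation for
perspective) and blends `(1−w)·image + w·color` (w default 0.5) where the
polygon is **nearer than or equal to** the surface depth `Z_V`; ties are
drawn on the surface.  The visibility rule is stated by its meaning
("polygon in front of the volume is visible"); formulations written for an
inverted depth axis flip the inequality symbol, not the behaviour.
Edge-on polygons (zero projected area) are skipped with a warning.

## Problem sizes and defaults

The recovery tests run the default thorax phantom (128 slices of 2 mm,
256×256 at 1.5 mm — a realistic chest FOV at modest resolution) and the
verification cube at its full 120×512×512 size; unit tests use scaled-down
phantoms (48×96×96) with the area cutoff scaled accordingly, since a 6 cm²
rule obviously removes organs that a quarter-scale phantom shrinks below
6 cm².  All randomness (noise, test instances) flows through explicit
integer seeds; results are bit-reproducible.

## Known limitations

* Boundary tracing assumes the structure forms one connected region per
  slice; per the single-contour-per-slice model, multiple disjoint regions
  of the same organ on one slice are not merged.
* The traced-and-filled mask has no interior holes by construction; organs
  with genuine internal cavities are delineated by their outer surface.
* Contour interpolation requires star-shaped contours; strongly concave
  key contours can alias under equiangular resampling.
* The semi-transparent opacity is per sample, so images depend on the step
  size (standard for this accumulation model); no opacity correction is
  applied.
* DICOM support covers single-frame axial CT series without gantry tilt;
  DICOM-RT structure sets and network transfer are out of scope.
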