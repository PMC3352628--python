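# ctsim

A CT virtual-simulation toolkit for radiotherapy treatment planning:
semi-automatic **boundary-tracking segmentation** of anatomical structures in
CT volumes, **contour** metrics, decimation and inter-slice interpolation,
**trilinear resampling** of anisotropic voxel stacks, and **volume rendering**
(digitally reconstructed radiographs, semi-transparent compositing, shaded
isosurfaces) with Z-buffer compositing of beam/block polygons.  Everything is
exercised on synthetic phantoms with exact ground truth, so the whole pipeline
is testable without patient data.

## Who this is for

Medical-physics and image-analysis developers who need a transparent,
dependency-light reference implementation of the classic CT-Sim computation
stack: the algorithms a virtual simulator runs between "load the CT series"
and "show the beam's-eye view".

## The core methods

**Hounsfield units.** A CT voxel stores
`HU = 1000 · (ρ_μ − ρ_water) / ρ_water`, the linear remap of the attenuation
coefficient ρ_μ that fixes water at 0 HU and air at −1000 HU.  The scanner
range [−1024, 3071] spans exactly 4096 = 2¹² values (12-bit voxels).

**Segmentation.** The user gives one seed point; per slice the pipeline is
HU-window thresholding (`I ≥ T ⇒ object`), a binary majority filter,
removal of regions smaller than an area cutoff (default 6 cm², suppressing
meaningless bright spots inside an organ), seed relocation into the nearest
object region when the seed lies on background, then **Moore 8-neighbour
boundary tracing** with the right-hand rule and Jacob's stopping criterion.
The filled region's centroid seeds the adjacent slices, so a single click
traces the structure in 3D.  A 6-connected **region grower**
(`|Δ grey| ≤ δ` to an adjacent accepted voxel) backs the seed handling.

**Contours.** Shoelace area (cm²), polyline periphery (cm), uniform-stride
decimation retaining `⌊N·(1−k/100)⌋` points, and inter-slice interpolation:
two key contours are resampled into the same number of equiangular sectors
about their centroids, sector points are joined into triangles, and the
triangle sides are intersected with the intermediate plane.

**Resampling.** The linear kernel `h(x) = 1 − |x|`, 1D/2D/3D linear
interpolation (`p_xyz = Σ corner · Π (coordinate or 1−coordinate)`), and
world-extent-preserving resampling of non-cubic voxels to an isotropic grid.

**Rendering.** DRR transparent mode `I = I₀ · exp(−∫ K_λ(t) dt)` by ray
marching; semi-transparent front-to-back accumulation
`I = Σ C_i α_i T_i`, `T_i = Π_{j<i}(1−α_j)`; gradient-shaded isosurfaces.
The first-surface depth goes to a Z-buffer `Z_V(i,j)`; a beam/block polygon
with scan-converted depth `Z_P(i,j)` is visible (blended into the image)
exactly where it is nearer than the volume surface, hidden where it is
behind it.

## Worked example

```python
import numpy as np
from ctsim import (PhantomSpec, generate_thorax, SeedPoint, SegmentationParams,
                   segment_structure, dice, contour_area, contour_periphery,
                   decimate)

vol, gt = generate_thorax(PhantomSpec.thorax())      # 128 x 256 x 256 phantom
rr, cc = np.nonzero(gt.masks["left_lung"].data[64])
seed = SeedPoint((64, int(rr.mean()), int(cc.mean())))
res = segment_structure(vol, seed, SegmentationParams(hu_window=(-950, -600)))

print("slices traced:", len(res.contours.contours))
print("Dice vs ground truth: %.4f" % dice(res.mask.data, gt.masks["left_lung"].data))
c = res.contours.contours[64]
print("mid-slice points:", len(c))
print("area %.1f cm^2, periphery %.1f cm" % (contour_area(c), contour_periphery(c)))
d = decimate(c, 20.0)
print("after 20%% decimation: %d points, area %.1f cm^2, periphery %.1f cm"
      % (len(d), contour_area(d), contour_periphery(d)))
```

prints

```
slices traced: 76
Dice vs ground truth: 0.9981
mid-slice points: 168
area 60.9 cm^2, periphery 29.5 cm
after 20% decimation: 134 points, area 60.9 cm^2, periphery 29.1 cm
```

One seed recovered the left lung through all 76 slices where it exists with
99.8 % Dice overlap against the phantom's analytic ground truth; removing
20 % of the mid-slice contour points leaves area and periphery essentially
unchanged (the decimated count follows the floor rule, ⌊168·0.8⌋ = 134).

The same operations are available from the shell:

```sh
ctsim phantom thorax --out ph
ctsim segment --volume ph/volume.json --seed-point 64,120,90 \
      --hu-window -950:-600 --name left_lung --out seg
ctsim contours metrics --in seg/contours_left_lung.json --out met
ctsim render drr --volume ph/volume.json --out img
```

Every run writes a `run_manifest.json` (parameters, version, seed) that
reproduces it bit-identically.

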