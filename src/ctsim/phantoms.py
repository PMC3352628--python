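"""Synthetic CT test volumes with known ground truth.

Two families:

* ``cubic_spheres`` — the verification phantom: a 120 x 120 x 120 mm water
  cube containing 2 mm spheres on a regular lattice, scanned at 1 mm slice
  thickness into 120 slices of 512 x 512 pixels.
* ``thorax`` — an anatomical stand-in for patient CT: an elliptic soft-
  tissue body on an air background, two ellipsoidal air-valued lungs (each a
  single 6-connected component), and a cylindrical bone-valued spine, with
  exact per-structure masks for segmentation recovery tests.

Voxelization is by center inclusion (a voxel is foreground when its center
lies inside the analytic surface), generation is a pure function of the
spec (Gaussian HU noise, when enabled, is drawn from the spec's seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .volume import BinaryMask, VoxelVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_cubic_phantom",
    "generate_thorax",
    "generate",
]

#: default tissue HU levels for the thorax phantom (plausible, well separated)
THORAX_HU = {"air": -1000.0, "lung": -800.0, "soft": 40.0, "bone": 700.0}


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic test volume.

    ``extent_mm`` is the world size (z, y, x); the matrix is (rows, cols);
    in-plane spacing follows as extent / matrix and the slice count as
    ceil(extent_z / slice_thickness).
    """

    kind: str
    extent_mm: tuple[float, float, float]
    slice_thickness_mm: float
    matrix: tuple[int, int]
    sphere_diameter_mm: float = 2.0
    sphere_pitch_mm: float = 10.0
    hu_levels: dict = field(default_factory=lambda: dict(THORAX_HU))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cubic_spheres", "thorax"):
            raise InvalidParameterError(f"unknown phantom kind {self.kind!r}")
        if any(e <= 0 for e in self.extent_mm):
            raise InvalidParameterError("extent_mm components must be > 0")
        if self.slice_thickness_mm <= 0:
            raise InvalidParameterError("slice_thickness_mm must be > 0")
        if any(m <= 0 for m in self.matrix):
            raise InvalidParameterError("matrix dimensions must be > 0")
        if self.kind == "cubic_spheres":
            if self.sphere_diameter_mm <= 0 or self.sphere_pitch_mm <= 0:
                raise InvalidParameterError(
                    "sphere diameter and pitch must be > 0"
                )
            if not self.sphere_diameter_mm < self.sphere_pitch_mm:
                raise InvalidParameterError(
                    "sphere_diameter_mm must be < sphere_pitch_mm"
                )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")

    @staticmethod
    def cubic(
        extent: float = 120.0,
        slice_thickness: float = 1.0,
        matrix: int = 512,
        sphere_diameter: float = 2.0,
        sphere_pitch: float = 10.0,
        noise_sd: float = 0.0,
        seed: int = 0,
    ) -> "PhantomSpec":
        """The verification cube: 120 mm, 1 mm slices, 512 x 512 matrix."""
        return PhantomSpec(
            "cubic_spheres",
            extent_mm=(extent, extent, extent),
            slice_thickness_mm=slice_thickness,
            matrix=(matrix, matrix),
            sphere_diameter_mm=sphere_diameter,
            sphere_pitch_mm=sphere_pitch,
            noise_sd=noise_sd,
            seed=seed,
        )

    @staticmethod
    def thorax(
        slices: int = 128,
        matrix: int = 256,
        slice_thickness: float = 2.0,
        pixel_mm: float = 1.5,
        noise_sd: float = 0.0,
        seed: int = 0,
    ) -> "PhantomSpec":
        """Default thorax: 128 slices of 2 mm, 256 x 256 at 1.5 mm pixels."""
        return PhantomSpec(
            "thorax",
            extent_mm=(slices * slice_thickness, matrix * pixel_mm, matrix * pixel_mm),
            slice_thickness_mm=slice_thickness,
            matrix=(matrix, matrix),
            noise_sd=noise_sd,
            seed=seed,
        )

    @property
    def n_slices(self) -> int:
        return int(np.ceil(self.extent_mm[0] / self.slice_thickness_mm))

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (
            self.slice_thickness_mm,
            self.extent_mm[1] / self.matrix[0],
            self.extent_mm[2] / self.matrix[1],
        )


@dataclass
class GroundTruth:
    """Named per-structure binary masks congruent with the phantom volume.

    Structures are pairwise disjoint.  For the thorax, ``body`` is the soft
    tissue between the skin and the interior structures; the full
    skin-enclosed region (what an outer-contour tracer delineates) is the
    union of all structures, available via :meth:`skin_mask`.
    """

    masks: dict[str, BinaryMask]

    def skin_mask(self) -> BinaryMask:
        union = None
        spacing = None
        for m in self.masks.values():
            spacing = m.spacing
            union = m.data.astype(bool) if union is None else union | m.data.astype(bool)
        return BinaryMask(union.astype(np.uint8), spacing=spacing)


def _axis_centers(n: int, spacing: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * spacing


def generate(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Dispatch on spec.kind."""
    if spec.kind == "cubic_spheres":
        return generate_cubic_phantom(spec)
    return generate_thorax(spec)


def generate_cubic_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Water cube with a regular lattice of high-HU spheres.

    Sphere centers sit at pitch/2 + k*pitch along each axis (all lattice
    points inside the extent); a voxel is sphere when its center lies within
    the sphere radius of the nearest lattice center.
    """
    if spec.kind != "cubic_spheres":
        raise InvalidParameterError("spec.kind must be 'cubic_spheres'")
    nz = spec.n_slices
    ny, nx = spec.matrix
    dz, dy, dx = spec.spacing
    pitch = spec.sphere_pitch_mm
    radius = spec.sphere_diameter_mm / 2.0

    def _dist_to_lattice(coords: np.ndarray, extent: float) -> np.ndarray:
        n_centers = max(1, int(np.floor((extent - pitch / 2.0) / pitch)) + 1)
        k = np.clip(np.round((coords - pitch / 2.0) / pitch), 0, n_centers - 1)
        return coords - (pitch / 2.0 + k * pitch)

    ddz = _dist_to_lattice(_axis_centers(nz, dz), spec.extent_mm[0])
    ddy = _dist_to_lattice(_axis_centers(ny, dy), spec.extent_mm[1])
    ddx = _dist_to_lattice(_axis_centers(nx, dx), spec.extent_mm[2])
    r2 = (
        ddz[:, None, None] ** 2
        + ddy[None, :, None] ** 2
        + ddx[None, None, :] ** 2
    )
    spheres = r2 <= radius**2
    hu = np.where(spheres, 1000.0, 0.0)  # bone-like spheres in water
    hu = _add_noise(hu, spec)
    vol = VoxelVolume(hu.astype(np.int16), spacing=(dz, dy, dx))
    gt = GroundTruth(
        {"spheres": BinaryMask(spheres.astype(np.uint8), spacing=(dz, dy, dx))}
    )
    return vol, gt


def generate_thorax(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Elliptic body with two ellipsoidal lungs and a cylindrical spine.

    Geometry (mm, relative to the in-plane volume center):

    * body: elliptic cylinder, semi-axes (y 120, x 150) scaled to the
      in-plane extent, spanning z in [z_ext/16, 15*z_ext/16);
    * lungs: ellipsoids, semi-axes (z 80, y 50, x 40) scaled to the volume,
      centered mid-stack at x = -/+ 60, y = -10;
    * spine: cylinder of radius 16 at y = +75 over the body's z span.

    All structure masks are pairwise disjoint; lungs are each one
    6-connected component.
    """
    if spec.kind != "thorax":
        raise InvalidParameterError("spec.kind must be 'thorax'")
    nz = spec.n_slices
    ny, nx = spec.matrix
    dz, dy, dx = spec.spacing
    ez, ey, ex = nz * dz, ny * dy, nx * dx
    hu = spec.hu_levels

    zc = _axis_centers(nz, dz)
    yc = _axis_centers(ny, dy) - ey / 2.0
    xc = _axis_centers(nx, dx) - ex / 2.0
    # scale the canonical geometry (designed for a 384 mm field, 256 mm stack)
    sy, sx, sz = ey / 384.0, ex / 384.0, ez / 256.0

    body_a_y, body_a_x = 120.0 * sy, 150.0 * sx
    z_lo, z_hi = ez / 16.0, 15.0 * ez / 16.0
    in_z = (zc >= z_lo) & (zc < z_hi)
    body2d = (
        (yc[:, None] / body_a_y) ** 2 + (xc[None, :] / body_a_x) ** 2
    ) <= 1.0
    body = in_z[:, None, None] & body2d[None, :, :]

    lung_az, lung_ay, lung_ax = 80.0 * sz, 50.0 * sy, 40.0 * sx
    lung_zc, lung_yc = ez / 2.0, -10.0 * sy
    lungs = {}
    for name, xoff in (("left_lung", -60.0 * sx), ("right_lung", 60.0 * sx)):
        m = (
            ((zc[:, None, None] - lung_zc) / lung_az) ** 2
            + ((yc[None, :, None] - lung_yc) / lung_ay) ** 2
            + ((xc[None, None, :] - xoff) / lung_ax) ** 2
        ) <= 1.0
        lungs[name] = m & body

    spine_r, spine_y = 16.0 * min(sy, sx), 75.0 * sy
    spine2d = ((yc[:, None] - spine_y) ** 2 + xc[None, :] ** 2) <= spine_r**2
    spine = in_z[:, None, None] & spine2d[None, :, :] & body

    interior = lungs["left_lung"] | lungs["right_lung"] | spine
    soft = body & ~interior

    vol_hu = np.full((nz, ny, nx), hu["air"], dtype=float)
    vol_hu[soft] = hu["soft"]
    vol_hu[lungs["left_lung"]] = hu["lung"]
    vol_hu[lungs["right_lung"]] = hu["lung"]
    vol_hu[spine] = hu["bone"]
    vol_hu = _add_noise(vol_hu, spec)

    spacing = (dz, dy, dx)
    vol = VoxelVolume(vol_hu, spacing=spacing)
    gt = GroundTruth(
        {
            "left_lung": BinaryMask(lungs["left_lung"].astype(np.uint8), spacing),
            "right_lung": BinaryMask(lungs["right_lung"].astype(np.uint8), spacing),
            "spine": BinaryMask(spine.astype(np.uint8), spacing),
            "body": BinaryMask(soft.astype(np.uint8), spacing),
        }
    )
    return vol, gt


def _add_noise(hu: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sd == 0:
        return hu
    rng = np.random.default_rng(spec.seed)
    return hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
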