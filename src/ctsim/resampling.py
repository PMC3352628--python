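"""Linear-family interpolation and resampling to isotropic voxels.

CT stacks usually have coarser spacing between slices than within them, so
voxels are not cubic and 3D renderings are distorted until the volume is
resampled.  The interpolators here are the linear family: the triangle
kernel h(x) = 1 - |x| on [-1, 1], 1D lerp, bilinear, and trilinear, and a
volume resampler that samples a new isotropic grid over the same world
extent through the trilinear interpolator with edge clamping.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InvalidParameterError
from .volume import VoxelVolume

__all__ = [
    "linear_kernel",
    "lerp",
    "bilerp",
    "trilerp",
    "sample_volume",
    "resample_to_isotropic",
]


def linear_kernel(x) -> np.ndarray:
    """Triangle interpolation kernel: h(x) = 1 - |x| for |x| <= 1, else 0."""
    ax = np.abs(np.asarray(x, dtype=float))
    return np.where(ax <= 1.0, 1.0 - ax, 0.0)


def _check_unit(name: str, v) -> None:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise InvalidParameterError(f"{name} must be in [0, 1] (no extrapolation)")


def lerp(p0, p1, x):
    """Linear interpolation (1 - x) * p0 + x * p1 for x in [0, 1]."""
    _check_unit("x", x)
    x = np.asarray(x, dtype=float)
    return (1.0 - x) * p0 + x * p1


def bilerp(p00, p01, p10, p11, x, y):
    """Bilinear interpolation on the unit square.

    First index of p is the x axis, second the y axis:
    (1-x)(1-y) p00 + (1-x) y p01 + x (1-y) p10 + x y p11.
    """
    _check_unit("x", x)
    _check_unit("y", y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (
        (1 - x) * (1 - y) * p00
        + (1 - x) * y * p01
        + x * (1 - y) * p10
        + x * y * p11
    )


def trilerp(p000, p001, p010, p011, p100, p101, p110, p111, x, y, z):
    """Trilinear interpolation on the unit cube.

    Corner ``pabc`` sits at (x, y, z) = (a, b, c); each corner is weighted by
    the product of (coordinate or 1-coordinate) per axis, so the weights sum
    to 1 and the result is a convex combination of the corners.  At z = 0 it
    reduces to the bilinear formula on the z = 0 face.
    """
    _check_unit("x", x)
    _check_unit("y", y)
    _check_unit("z", z)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    return (
        (1 - x) * (1 - y) * (1 - z) * p000
        + (1 - x) * (1 - y) * z * p001
        + (1 - x) * y * (1 - z) * p010
        + (1 - x) * y * z * p011
        + x * (1 - y) * (1 - z) * p100
        + x * (1 - y) * z * p101
        + x * y * (1 - z) * p110
        + x * y * z * p111
    )


def sample_volume(volume: VoxelVolume, world_points: np.ndarray) -> np.ndarray:
    """Trilinearly sample a volume at world-mm points (..., 3) in (z, y, x).

    Out-of-support positions (closer than half a voxel to the border, or
    outside the volume) are edge-clamped.
    """
    data = np.asarray(volume.data, dtype=float)
    pts = np.atleast_2d(np.asarray(world_points, dtype=float))
    idx = (pts - np.asarray(volume.origin)) / np.asarray(volume.spacing) - 0.5
    out = _sample_fractional(data, idx)
    return out.reshape(np.asarray(world_points).shape[:-1])


def _sample_fractional(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear sampling at fractional (z, y, x) voxel indices, clamped."""
    nz, ny, nx = data.shape
    z = np.clip(idx[..., 0], 0, nz - 1)
    y = np.clip(idx[..., 1], 0, ny - 1)
    x = np.clip(idx[..., 2], 0, nx - 1)
    z0 = np.clip(np.floor(z).astype(int), 0, max(nz - 2, 0))
    y0 = np.clip(np.floor(y).astype(int), 0, ny - 2)
    x0 = np.clip(np.floor(x).astype(int), 0, nx - 2)
    z1 = np.minimum(z0 + 1, nz - 1)
    y1, x1 = y0 + 1, x0 + 1
    fz, fy, fx = z - z0, y - y0, x - x0
    return trilerp(
        data[z0, y0, x0], data[z1, y0, x0],
        data[z0, y1, x0], data[z1, y1, x0],
        data[z0, y0, x1], data[z1, y0, x1],
        data[z0, y1, x1], data[z1, y1, x1],
        fx, fy, fz,
    )


def resample_to_isotropic(
    volume: VoxelVolume, target_spacing: float
) -> VoxelVolume:
    """Resample a volume onto an isotropic grid over the same world extent.

    The new grid has ``round(extent / target_spacing)`` voxels per axis
    (at least 1), voxel centers at ``origin + (i + 0.5) * target_spacing``,
    values trilinearly interpolated from the source with edge clamping.
    """
    if target_spacing <= 0:
        raise InvalidParameterError("target_spacing must be > 0")
    extent = volume.extent_mm()
    if target_spacing > 2.0 * max(extent):
        raise InvalidParameterError(
            f"target spacing {target_spacing} mm is coarser than twice the "
            f"volume extent {max(extent)} mm"
        )
    shape_new = tuple(max(1, int(round(e / target_spacing))) for e in extent)
    axes = [
        np.asarray(o) + (np.arange(n) + 0.5) * target_spacing
        for n, o in zip(shape_new, volume.origin)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    idx = (pts - np.asarray(volume.origin)) / np.asarray(volume.spacing) - 0.5
    data = _sample_fractional(np.asarray(volume.data, dtype=float), idx)
    return VoxelVolume(
        data,
        spacing=(target_spacing,) * 3,
        origin=volume.origin,
        bits=volume.bits,
    )
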