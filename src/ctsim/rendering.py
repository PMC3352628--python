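"""Volume rendering: DRR, semi-transparent compositing, isosurface shading,
and Z-buffer compositing of beam/block polygons.

All renderers cast one ray per image pixel through the HU volume and sample
it trilinearly at a fixed step (mm).

* Transparent mode (DRR): Beer-Lambert attenuation,
  ``I = I0 * exp(-integral of K(t) dt)`` along the ray, with the line
  integral approximated by a Riemann sum; there is no surface, so the depth
  buffer stays at the far plane.
* Semi-transparent mode: front-to-back accumulation
  ``I = sum C_i * alpha_i * T_i`` with transparency
  ``T_i = prod_{j<i} (1 - alpha_j)``, early ray termination at T < 1e-3,
  and the depth buffer set where accumulated opacity first crosses 0.5.
* Isosurface mode: first isovalue crossing (sign change between samples,
  refined by one linear sub-step), Lambertian shading ``|g . L|`` from the
  central-difference gradient at the hit; the depth buffer records the hit.

Depth increases away from the viewer.  A beam/block polygon pixel is visible
— and blended into the image — exactly where its depth is nearer than (or
equal to) the volume's first-surface depth; where it is farther it is hidden
behind the volume and the image is untouched.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

from .errors import InvalidParameterError
from .resampling import sample_volume
from .volume import VoxelVolume

__all__ = [
    "Camera",
    "CameraFrame",
    "TransferFunction",
    "RenderResult",
    "BeamPolygon",
    "RenderWarning",
    "render_drr",
    "render_semitransparent",
    "render_isosurface",
    "composite_polygons",
]


class RenderWarning(UserWarning):
    pass


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidParameterError("zero-length direction vector")
    return v / n


@dataclass
class Camera:
    """Viewing geometry.  Vectors are world mm in (z, y, x) order.

    ``direction`` points from the viewer into the scene.  For ``parallel``
    mode all rays share it; for ``perspective`` mode rays fan out from
    ``source`` (placed ``focal`` mm behind the image plane when not given)
    through the pixel grid — the beam's-eye-view geometry.  The image plane
    is centered on the volume unless ``center`` is given.
    """

    direction: tuple[float, float, float]
    shape: tuple[int, int] = (64, 64)
    pitch: float = 2.0
    mode: str = "parallel"
    up: tuple[float, float, float] | None = None
    center: tuple[float, float, float] | None = None
    source: tuple[float, float, float] | None = None
    focal: float = 1000.0

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "perspective"):
            raise InvalidParameterError(f"unknown camera mode {self.mode!r}")
        if self.pitch <= 0:
            raise InvalidParameterError("pixel pitch must be > 0")
        if any(n < 1 for n in self.shape):
            raise InvalidParameterError("image shape must be >= 1x1")
        self.direction = tuple(_unit(self.direction))

    def frame_for(self, volume: VoxelVolume) -> "CameraFrame":
        """Resolve the orthonormal frame and plane placement for a volume."""
        w = np.asarray(self.direction)
        if self.up is not None:
            up = _unit(self.up)
        else:
            # pick the world axis least aligned with the view direction
            axes = np.eye(3)
            up = axes[int(np.argmin(np.abs(w)))]
        u = np.cross(up, w)
        if np.linalg.norm(u) < 1e-9:
            raise InvalidParameterError("up vector parallel to view direction")
        u = _unit(u)
        v = np.cross(w, u)
        extent = np.asarray(volume.extent_mm())
        vol_center = np.asarray(volume.origin) + extent / 2.0
        standoff = float(np.linalg.norm(extent))
        if self.center is not None:
            plane_center = np.asarray(self.center, dtype=float)
        else:
            plane_center = vol_center - w * standoff
        source = None
        if self.mode == "perspective":
            if self.source is not None:
                source = np.asarray(self.source, dtype=float)
            else:
                source = plane_center - w * self.focal
        return CameraFrame(
            u=u, v=v, w=w, plane_center=plane_center,
            shape=tuple(self.shape), pitch=float(self.pitch),
            mode=self.mode, source=source,
        )


@dataclass
class CameraFrame:
    """Resolved camera basis: u (image columns), v (image rows), w (view)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    plane_center: np.ndarray
    shape: tuple[int, int]
    pitch: float
    mode: str
    source: np.ndarray | None = None

    def pixel_points(self) -> np.ndarray:
        """World positions (H, W, 3) of the pixel centers on the image plane."""
        h, wd = self.shape
        jj, ii = np.meshgrid(np.arange(wd), np.arange(h))
        du = (jj - (wd - 1) / 2.0) * self.pitch
        dv = (ii - (h - 1) / 2.0) * self.pitch
        return (
            self.plane_center
            + du[..., None] * self.u
            + dv[..., None] * self.v
        )

    def rays(self) -> tuple[np.ndarray, np.ndarray]:
        """(origins, unit directions), each (H, W, 3)."""
        pts = self.pixel_points()
        if self.mode == "parallel":
            dirs = np.broadcast_to(self.w, pts.shape).copy()
            return pts, dirs
        d = pts - self.source
        dirs = d / np.linalg.norm(d, axis=-1, keepdims=True)
        origins = np.broadcast_to(self.source, pts.shape).copy()
        return origins, dirs

    def project(self, points: np.ndarray):
        """Project world points to (col_px, row_px, depth)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        h, wd = self.shape
        if self.mode == "parallel":
            rel = p - self.plane_center
            depth = rel @ self.w
            uc = rel @ self.u / self.pitch + (wd - 1) / 2.0
            vc = rel @ self.v / self.pitch + (h - 1) / 2.0
            return uc, vc, depth
        rel = p - self.source
        depth = np.linalg.norm(rel, axis=-1)
        along = rel @ self.w
        if np.any(along <= 1e-9):
            raise InvalidParameterError("point behind the perspective source")
        focal = float((self.plane_center - self.source) @ self.w)
        scale = focal / along
        uc = (rel @ self.u) * scale / self.pitch + (wd - 1) / 2.0
        vc = (rel @ self.v) * scale / self.pitch + (h - 1) / 2.0
        return uc, vc, depth


@dataclass
class TransferFunction:
    """Piecewise-linear maps from HU to optical properties.

    ``attenuation`` maps HU -> K (1/mm, >= 0) for the DRR line integral;
    ``shade``/``opacity`` map HU -> C and alpha in [0, 1] for the
    semi-transparent mode; ``isovalue`` selects the surface for isosurface
    rendering.  Each map is a sequence of (hu, value) breakpoints, clamped
    outside its range.
    """

    attenuation: list[tuple[float, float]] | None = None
    shade: list[tuple[float, float]] | None = None
    opacity: list[tuple[float, float]] | None = None
    isovalue: float | None = None

    def __post_init__(self) -> None:
        for name, pts, lo, hi in (
            ("attenuation", self.attenuation, 0.0, np.inf),
            ("shade", self.shade, -np.inf, np.inf),
            ("opacity", self.opacity, 0.0, 1.0),
        ):
            if pts is None:
                continue
            arr = np.asarray(pts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
                raise InvalidParameterError(f"{name} needs (hu, value) pairs")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise InvalidParameterError(f"{name} breakpoints must increase")
            if np.any(arr[:, 1] < lo) or np.any(arr[:, 1] > hi):
                raise InvalidParameterError(
                    f"{name} values must lie in [{lo}, {hi}]"
                )

    def _eval(self, pts, hu):
        arr = np.asarray(pts, dtype=float)
        return np.interp(hu, arr[:, 0], arr[:, 1])

    def attenuation_of(self, hu):
        if self.attenuation is None:
            raise InvalidParameterError("transfer function has no attenuation map")
        return self._eval(self.attenuation, hu)

    def shade_of(self, hu):
        if self.shade is None:
            return np.ones_like(np.asarray(hu, dtype=float))
        return self._eval(self.shade, hu)

    def opacity_of(self, hu):
        if self.opacity is None:
            raise InvalidParameterError("transfer function has no opacity map")
        return self._eval(self.opacity, hu)

    @staticmethod
    def uniform_attenuation(k: float, hu_threshold: float = -1024.0) -> "TransferFunction":
        """Constant attenuation k for HU >= threshold (slab experiments)."""
        return TransferFunction(
            attenuation=[(hu_threshold - 1.0, 0.0), (hu_threshold, k), (3071.0, k)]
        )


@dataclass
class RenderResult:
    """A rendered image plus its first-surface depth buffer.

    ``zbuffer`` holds, per pixel, the depth (mm along the ray, increasing
    away from the viewer) of the first rendered surface, or ``far`` where no
    surface was met.  ``frame`` records the camera geometry the image was
    rendered with so polygons can be composited afterwards.
    """

    image: np.ndarray
    zbuffer: np.ndarray
    far: float
    frame: CameraFrame | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.zbuffer.shape:
            raise InvalidParameterError("image and zbuffer must be congruent")


@dataclass
class BeamPolygon:
    """A planar beam or block polygon in volume mm coordinates."""

    vertices: np.ndarray
    color: float = 1.0
    role: str = "beam"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 3:
            raise InvalidParameterError("polygon needs >= 3 (z, y, x) vertices")
        if self.role not in ("beam", "block"):
            raise InvalidParameterError(f"unknown polygon role {self.role!r}")
        if len(v) > 3:
            # planarity within tolerance
            n = np.cross(v[1] - v[0], v[2] - v[0])
            nn = np.linalg.norm(n)
            if nn > 1e-12:
                d = np.abs((v - v[0]) @ (n / nn))
                scale = max(1.0, float(np.abs(v).max()))
                if np.any(d > 1e-6 * scale + 1e-9):
                    raise InvalidParameterError("polygon vertices are not planar")
        self.vertices = v


# ---------------------------------------------------------------------------
# Ray marching
# ---------------------------------------------------------------------------

def _ray_box(origins, dirs, lo, hi):
    """Entry/exit parameters of rays against an axis-aligned box (slab test)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t_a = (lo - origins) * inv
        t_b = (hi - origins) * inv
    tmin = np.where(np.isnan(t_a), -np.inf, np.minimum(t_a, t_b)).max(axis=-1)
    tmax = np.where(np.isnan(t_b), np.inf, np.maximum(t_a, t_b)).min(axis=-1)
    # rays parallel to a slab and outside it never hit
    par = np.abs(dirs) < 1e-15
    outside = par & ((origins < lo) | (origins > hi))
    miss = outside.any(axis=-1) | (tmax <= np.maximum(tmin, 0.0))
    t0 = np.where(miss, 0.0, np.maximum(tmin, 0.0))
    t1 = np.where(miss, 0.0, tmax)
    return t0, t1


def _setup(volume: VoxelVolume, camera: Camera):
    frame = camera.frame_for(volume)
    origins, dirs = frame.rays()
    lo = np.asarray(volume.origin, dtype=float)
    hi = lo + np.asarray(volume.extent_mm())
    t0, t1 = _ray_box(origins, dirs, lo, hi)
    far = float(t1.max()) if t1.max() > 0 else float(np.linalg.norm(hi - lo))
    return frame, origins, dirs, t0, t1, far


def render_drr(
    volume: VoxelVolume,
    camera: Camera,
    tf: TransferFunction,
    step: float,
    I0: float = 1.0,
) -> RenderResult:
    """Digitally reconstructed radiograph (transparent mode).

    Per pixel the attenuation line integral is accumulated as a Riemann sum
    of ``K(sample) * step`` over ray samples inside the volume (the last
    partial step is weighted by its true width), and
    ``I = I0 * exp(-integral)``.  Transparent mode has no surface: the depth
    buffer is the far plane everywhere.
    """
    if step <= 0:
        raise InvalidParameterError("step must be > 0")
    frame, origins, dirs, t0, t1, far = _setup(volume, camera)
    acc = np.zeros(frame.shape, dtype=float)
    span = t1 - t0
    n_steps = int(np.ceil(span.max() / step)) if span.max() > 0 else 0
    for k in range(n_steps):
        tk = t0 + k * step
        wk = np.clip(t1 - tk, 0.0, step)
        active = wk > 0
        if not active.any():
            break
        mid = tk[active] + wk[active] / 2.0
        pts = origins[active] + mid[:, None] * dirs[active]
        hu = sample_volume(volume, pts)
        acc[active] += tf.attenuation_of(hu) * wk[active]
    image = I0 * np.exp(-acc)
    zbuffer = np.full(frame.shape, far)
    return RenderResult(image=image, zbuffer=zbuffer, far=far, frame=frame)


def render_semitransparent(
    volume: VoxelVolume,
    camera: Camera,
    tf: TransferFunction,
    step: float,
) -> RenderResult:
    """Semi-transparent front-to-back accumulation.

    ``I = sum_i C_i * alpha_i * T_i`` with ``T_i = prod_{j<i} (1 - alpha_j)``
    over ray samples (opacity is per sample, not rescaled by step).  Rays
    terminate early once T < 1e-3.  The depth buffer records the first
    sample where the accumulated opacity (1 - T) crosses 0.5.
    """
    if step <= 0:
        raise InvalidParameterError("step must be > 0")
    frame, origins, dirs, t0, t1, far = _setup(volume, camera)
    image = np.zeros(frame.shape, dtype=float)
    transparency = np.ones(frame.shape, dtype=float)
    zbuffer = np.full(frame.shape, far)
    unset = np.ones(frame.shape, dtype=bool)
    span = t1 - t0
    n_steps = int(np.ceil(span.max() / step)) if span.max() > 0 else 0
    for k in range(n_steps):
        tk = t0 + k * step
        wk = np.clip(t1 - tk, 0.0, step)
        active = (wk > 0) & (transparency > 1e-3)
        if not active.any():
            break
        mid = tk[active] + wk[active] / 2.0
        pts = origins[active] + mid[:, None] * dirs[active]
        hu = sample_volume(volume, pts)
        a = tf.opacity_of(hu)
        c = tf.shade_of(hu)
        T = transparency[active]
        image[active] += c * a * T
        T_new = T * (1.0 - a)
        transparency[active] = T_new
        crossed = np.zeros(frame.shape, dtype=bool)
        crossed[active] = (1.0 - T_new) >= 0.5
        newly = crossed & unset
        zb_depth = np.zeros(frame.shape)
        zb_depth[active] = mid
        zbuffer[newly] = zb_depth[newly]
        unset &= ~newly
    return RenderResult(image=image, zbuffer=zbuffer, far=far, frame=frame)


def render_isosurface(
    volume: VoxelVolume,
    camera: Camera,
    isovalue: float,
    step: float,
    light: tuple[float, float, float] | None = None,
) -> RenderResult:
    """Gradient-shaded isosurface (first-hit ray casting).

    Each ray stops at the first sign change of ``sample - isovalue``; the
    hit position is refined by one linear sub-step, shaded with the
    Lambertian term ``|g . L|`` where g is the normalized central-difference
    gradient at the hit and L the light direction (the viewing direction by
    default), and its depth goes to the Z-buffer.  Pixels whose rays never
    cross the isovalue stay at background 0 and far depth.
    """
    if step <= 0:
        raise InvalidParameterError("step must be > 0")
    frame, origins, dirs, t0, t1, far = _setup(volume, camera)
    h, wd = frame.shape
    flat_o = origins.reshape(-1, 3)
    flat_d = dirs.reshape(-1, 3)
    ft0, ft1 = t0.ravel(), t1.ravel()
    n = flat_o.shape[0]
    t_hit = np.full(n, np.nan)
    prev_val = np.full(n, np.nan)
    prev_t = np.full(n, np.nan)
    alive = ft1 > ft0
    span = ft1 - ft0
    n_steps = int(np.ceil(span.max() / step)) + 1 if span.max() > 0 else 0
    for k in range(n_steps):
        t = ft0 + k * step
        cur = alive & (t <= ft1)
        if not cur.any():
            break
        pts = flat_o[cur] + t[cur, None] * flat_d[cur]
        val = sample_volume(volume, pts) - isovalue
        pv = prev_val[cur]
        pt = prev_t[cur]
        have_prev = ~np.isnan(pv)
        crossing = have_prev & (np.sign(pv) != np.sign(val)) & (pv != val)
        first_in = ~have_prev & (val >= 0)  # already inside at entry
        frac = np.zeros(val.shape)
        denom = val - pv
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(crossing, -pv / np.where(denom == 0, 1, denom), 0.0)
        hit_t = np.where(crossing, pt + frac * (t[cur] - pt), t[cur])
        hit_now = crossing | first_in
        idx = np.flatnonzero(cur)
        hit_idx = idx[hit_now]
        t_hit[hit_idx] = hit_t[hit_now]
        alive[hit_idx] = False
        prev_val[idx] = val
        prev_t[idx] = t[cur]
    image = np.zeros(n)
    zbuffer = np.full(n, far)
    hit = ~np.isnan(t_hit)
    if hit.any():
        pts = flat_o[hit] + t_hit[hit, None] * flat_d[hit]
        g = _gradient_at(volume, pts)
        gn = np.linalg.norm(g, axis=-1, keepdims=True)
        gn[gn < 1e-12] = 1.0
        g = g / gn
        if light is None:
            lvec = -flat_d[hit]
        else:
            lvec = np.broadcast_to(_unit(light), g.shape)
        image[hit] = np.abs(np.sum(g * lvec, axis=-1))
        zbuffer[hit] = t_hit[hit]
    return RenderResult(
        image=image.reshape(h, wd),
        zbuffer=zbuffer.reshape(h, wd),
        far=far,
        frame=frame,
    )


def _gradient_at(volume: VoxelVolume, pts: np.ndarray) -> np.ndarray:
    """Central-difference HU gradient (z, y, x per mm) at world points."""
    h = 0.5 * min(volume.spacing)
    g = np.empty_like(pts)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = h
        g[:, ax] = (sample_volume(volume, pts + e) - sample_volume(volume, pts - e)) / (
            2.0 * h
        )
    return g


# ---------------------------------------------------------------------------
# Polygon Z-buffer compositing
# ---------------------------------------------------------------------------

def composite_polygons(
    render: RenderResult,
    polys: list[BeamPolygon],
    w: float = 0.5,
) -> np.ndarray:
    """Blend beam/block polygons over a rendered image using the Z-buffer.

    Each polygon is projected with the render's camera frame and
    scan-converted to a per-pixel depth Z_P (the polygon's plane
    interpolated across its footprint).  Where the polygon is nearer than
    the volume's first surface (Z_P <= Z_V, ties drawn) the pixel becomes
    ``(1 - w) * image + w * polygon_color``; where it is behind the surface
    the pixel is untouched.  Edge-on (unprojectable) polygons are skipped
    with a :class:`RenderWarning`.
    """
    if render.frame is None:
        raise InvalidParameterError("render result carries no camera frame")
    if not 0.0 <= w <= 1.0:
        raise InvalidParameterError("blend weight must be in [0, 1]")
    frame = render.frame
    out = render.image.astype(float).copy()
    h, wd = frame.shape
    for poly in polys:
        uc, vc, depth = frame.project(poly.vertices)
        verts_rc = np.column_stack([vc, uc])
        area2 = 0.0
        for k in range(1, len(uc) - 1):
            a = verts_rc[k] - verts_rc[0]
            b = verts_rc[k + 1] - verts_rc[0]
            area2 += a[0] * b[1] - a[1] * b[0]
        if abs(area2) < 1e-9:
            _warnings.warn(
                f"{poly.role} polygon is edge-on to the view; skipped",
                RenderWarning,
            )
            continue
        verts_closed = np.vstack([verts_rc, verts_rc[:1]])
        inside = skmeasure.grid_points_in_poly((h, wd), verts_closed)
        if not inside.any():
            continue
        # per-pixel polygon depth from the (affine in u, v) plane fit
        A = np.column_stack([uc, vc, np.ones(len(uc))])
        coeff, *_ = np.linalg.lstsq(A, depth, rcond=None)
        rr, cc = np.nonzero(inside)
        z_p = coeff[0] * cc + coeff[1] * rr + coeff[2]
        z_v = render.zbuffer[rr, cc]
        vis = z_p <= z_v
        out[rr[vis], cc[vis]] = (1.0 - w) * out[rr[vis], cc[vis]] + w * poly.color
    return out
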