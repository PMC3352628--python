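"""Boundary-tracking segmentation with seed handling and region growing.

The segmenter is semi-automatic: the user supplies one seed point inside (or
near) the structure of interest and the algorithm traces the object boundary
on every slice where the structure persists.

Per slice the pipeline is: HU-window threshold -> optional box smoothing ->
seed resolution (a seed on background is relocated into the nearest object
region; regions smaller than an area cutoff, by default 6 cm^2, are removed
so small bright spots inside an organ are ignored) -> Moore-neighbor
boundary tracing with the right-hand rule and Jacob's stopping criterion ->
optional point decimation.  The seed for the next slice is the centroid of
the current slice's filled region.

``region_grow`` is the classic 6-connected seeded grower: a voxel joins when
its grey-level difference to an adjacent already-accepted voxel is within a
tolerance; the accepted set is the reachability closure and therefore
independent of visit order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contours import Contour, ContourSet, fill_polygon_slice
from .errors import InvalidParameterError, NoObjectError, OutOfBoundsError
from .filters import band_mask, smooth
from .volume import BinaryMask, VoxelVolume

__all__ = [
    "SeedPoint",
    "SegmentationParams",
    "SegmentationResult",
    "track_boundary",
    "relocate_seed_outside",
    "remove_small_regions",
    "region_grow",
    "segment_structure",
    "dice",
]

# 8-neighborhood in clockwise order on screen (row down), starting East
_MOORE = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedPoint:
    """A user seed: (slice, row, col) voxel index plus a hint whether it is
    expected to lie outside or inside the target region."""

    position: tuple[int, int, int]
    mode_hint: str = "auto"

    def __post_init__(self) -> None:
        if self.mode_hint not in ("auto", "outside", "inside"):
            raise InvalidParameterError(f"bad mode_hint {self.mode_hint!r}")
        if len(self.position) != 3:
            raise InvalidParameterError("seed position must be (slice, row, col)")


@dataclass
class SegmentationParams:
    """Knobs of the per-slice pipeline.

    hu_window : (low, high) HU band defining "object" (>= low and <= high).
    min_region_area_cm2 : regions with area <= this are treated as noise
        spots and removed before tracing (default 6 cm^2).
    rg_delta : grey-level tolerance for region growing, HU.
    connectivity : in-plane connectivity for components (4 or 8).
    smooth_size : odd box size for pre-threshold smoothing (1 disables).
    decimate_percent : k% of contour points removed after tracing.
    """

    hu_window: tuple[float, float]
    min_region_area_cm2: float = 6.0
    rg_delta: float = 50.0
    connectivity: int = 8
    smooth_size: int = 3
    decimate_percent: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.hu_window
        if not lo < hi:
            raise InvalidParameterError(f"hu_window low must be < high: ({lo}, {hi})")
        if self.min_region_area_cm2 <= 0:
            raise InvalidParameterError("min_region_area_cm2 must be > 0")
        if self.rg_delta < 0:
            raise InvalidParameterError("rg_delta must be >= 0")
        if self.connectivity not in (4, 8):
            raise InvalidParameterError("in-plane connectivity must be 4 or 8")
        if self.smooth_size < 1 or self.smooth_size % 2 == 0:
            raise InvalidParameterError("smooth_size must be odd and >= 1")
        if not 0 <= self.decimate_percent < 100:
            raise InvalidParameterError("decimate_percent must be in [0, 100)")


@dataclass
class SegmentationResult:
    """Output of :func:`segment_structure`: per-slice contours, the filled
    3D mask, and any warnings (e.g. the structure vanishing mid-stack)."""

    contours: ContourSet
    mask: BinaryMask
    warnings: list[str] = field(default_factory=list)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary arrays."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


# ---------------------------------------------------------------------------
# Boundary tracking
# ---------------------------------------------------------------------------

def _is_object(mask: np.ndarray, r: int, c: int) -> bool:
    if r < 0 or c < 0 or r >= mask.shape[0] or c >= mask.shape[1]:
        return False  # outside the image counts as background
    return mask[r, c] != 0


def _probe_start(mask: np.ndarray, start: tuple[int, int]):
    """Find the tracing start: an object boundary pixel plus the background
    pixel it was entered from.

    From a background start, rays are cast in the four axial directions
    (+x, +y, -x, -y priority) and the nearest object hit wins.  From an
    object start, the probe walks +x inside the object to its edge.
    """
    h, w = mask.shape
    r0, c0 = int(start[0]), int(start[1])
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise OutOfBoundsError(f"start {start} outside slice {mask.shape}")
    if mask[r0, c0]:
        # start the trace on the *outer* boundary of the seed's component:
        # its topmost-leftmost pixel, entered from the background above
        labels, _ = ndimage.label(mask, structure=_STRUCT8)
        rr, cc = np.nonzero(labels == labels[r0, c0])
        j = np.lexsort((cc, rr))[0]
        return (int(rr[j]), int(cc[j])), (int(rr[j]) - 1, int(cc[j]))
    best = None  # (distance, priority, hit, entered_from)
    for prio, (dr, dc) in enumerate(((0, 1), (1, 0), (0, -1), (-1, 0))):
        r, c = r0, c0
        dist = 0
        while True:
            r += dr
            c += dc
            dist += 1
            if not (0 <= r < h and 0 <= c < w):
                break
            if mask[r, c]:
                cand = (dist, prio, (r, c), (r - dr, c - dc))
                if best is None or cand[:2] < best[:2]:
                    best = cand
                break
    if best is None:
        raise NoObjectError("no object pixel found along the axial probe rays")
    return best[2], best[3]


def track_boundary(
    mask: BinaryMask | np.ndarray, start: tuple[int, int]
) -> list[tuple[int, int]]:
    """Trace the closed boundary of the object region hit by the start probe.

    Moore 8-neighbor following with a clockwise scan starting from the
    backtrack (background) direction — the region stays consistently on one
    side — and Jacob's stopping criterion (stop on re-entering the start
    pixel from the start direction).  Returns the ordered boundary pixel
    positions with the first position repeated at the end; every returned
    pixel is an object pixel 4-adjacent to background.
    """
    m = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if m.ndim != 2:
        raise InvalidParameterError("boundary tracking works on a single slice")
    if not m.any():
        raise NoObjectError("mask contains no object pixels")
    s, b = _probe_start(m, start)
    path = [s]
    cur, back = s, b
    seen = {(s, b): 0}
    limit = 8 * m.size + 8
    first = 0
    for _ in range(limit):
        off = (back[0] - cur[0], back[1] - cur[1])
        start_i = _MOORE_INDEX[off]
        nxt = None
        prev = back
        for k in range(1, 9):
            dr, dc = _MOORE[(start_i + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if _is_object(m, cand[0], cand[1]):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated single pixel
            break
        cur, back = nxt, prev
        state = (cur, back)
        if state in seen:
            # Jacob's criterion: re-entering a visited pixel from the same
            # direction closes the cycle (normally the start state itself)
            first = seen[state]
            break
        seen[state] = len(path)
        path.append(cur)
    cycle = path[first:]
    cycle.append(cycle[0])
    return cycle


# ---------------------------------------------------------------------------
# Seed handling
# ---------------------------------------------------------------------------

def relocate_seed_outside(
    mask: BinaryMask | np.ndarray, seed: tuple[int, int]
) -> tuple[int, int]:
    """Move a background seed into the nearest object region's interior.

    Rings of increasing radius around the seed are scanned row-major (the
    background is grown outward) until the first object pixel is touched;
    the returned pixel is then pulled strictly inside that region (all four
    neighbors object) so later tracing does not start on a ragged edge.  A
    seed already on an object pixel is returned unchanged.
    """
    m = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if not m.any():
        raise NoObjectError("mask contains no object pixels")
    r0, c0 = int(seed[0]), int(seed[1])
    h, w = m.shape
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise OutOfBoundsError(f"seed {seed} outside slice {m.shape}")
    if m[r0, c0]:
        return (r0, c0)
    rows, cols = np.nonzero(m)
    cheb = np.maximum(np.abs(rows - r0), np.abs(cols - c0))
    ring = cheb.min()
    on_ring = cheb == ring
    order = np.lexsort((cols[on_ring], rows[on_ring]))  # row-major scan
    hit = (int(rows[on_ring][order[0]]), int(cols[on_ring][order[0]]))

    labels, _ = ndimage.label(m, structure=_STRUCT8)
    region = labels == labels[hit]
    interior = ndimage.binary_erosion(region)  # 4-connected erosion
    if interior.any():
        ir, ic = np.nonzero(interior)
        j = np.argmin((ir - hit[0]) ** 2 + (ic - hit[1]) ** 2)
        return (int(ir[j]), int(ic[j]))
    return hit  # thin region with no strict interior


def remove_small_regions(
    mask: BinaryMask | np.ndarray,
    spacing: tuple[float, float],
    max_area_cm2: float = 6.0,
) -> BinaryMask:
    """Drop every 8-connected object region with area <= ``max_area_cm2``.

    Pixel area is dy*dx mm^2 from ``spacing``; small bright spots inside an
    organ are meaningless for organ delineation and would derail tracing.
    """
    m = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    dy, dx = float(spacing[0]), float(spacing[1])
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        return BinaryMask(np.zeros_like(m, dtype=np.uint8), spacing=(dy, dx))
    counts = np.bincount(labels.ravel())
    areas_cm2 = counts * dy * dx / 100.0
    keep = areas_cm2 > max_area_cm2
    keep[0] = False
    out = keep[labels].astype(np.uint8)
    return BinaryMask(out, spacing=(dy, dx))


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

def region_grow(
    volume: VoxelVolume | np.ndarray,
    seed: tuple[int, int, int],
    delta: float,
    compare_to: str = "neighbor",
) -> BinaryMask:
    """6-connected seeded region growing on grey levels.

    With ``compare_to='neighbor'`` (the default) a voxel joins when its
    absolute grey-level difference to an adjacent already-accepted voxel is
    within ``delta``; the accepted set is then the set of voxels reachable
    from the seed by 6-connected steps of difference <= delta, independent
    of visit order.  ``compare_to='seed'`` compares against the seed value
    instead.  ``delta=0`` grows the seed's exact-value component.
    """
    if isinstance(volume, VoxelVolume):
        data = np.asarray(volume.data, dtype=float)
        spacing = volume.spacing
    else:
        data = np.asarray(volume, dtype=float)
        spacing = (1.0, 1.0, 1.0)
    if delta < 0:
        raise InvalidParameterError("delta must be >= 0")
    if compare_to not in ("neighbor", "seed"):
        raise InvalidParameterError("compare_to must be 'neighbor' or 'seed'")
    z, y, x = (int(v) for v in seed)
    if not (
        0 <= z < data.shape[0] and 0 <= y < data.shape[1] and 0 <= x < data.shape[2]
    ):
        raise OutOfBoundsError(f"seed {seed} outside volume {data.shape}")

    if compare_to == "seed":
        # one shot: the accepted criterion is local, grow the connected
        # component of |v - v_seed| <= delta containing the seed
        ok = np.abs(data - data[z, y, x]) <= delta
        labels, _ = ndimage.label(ok)  # 6-connected (default structure)
        accepted = labels == labels[z, y, x]
        return BinaryMask(accepted.astype(np.uint8), spacing=spacing)

    accepted = np.zeros(data.shape, dtype=bool)
    accepted[z, y, x] = True
    frontier = accepted.copy()
    while frontier.any():
        new = np.zeros_like(accepted)
        for axis in range(3):
            for shift in (1, -1):
                src = _shift_slices(frontier.shape, axis, shift, source=True)
                dst = _shift_slices(frontier.shape, axis, shift, source=False)
                cand = (
                    frontier[src]
                    & ~accepted[dst]
                    & (np.abs(data[dst] - data[src]) <= delta)
                )
                new[dst] |= cand
        accepted |= new
        frontier = new
    return BinaryMask(accepted.astype(np.uint8), spacing=spacing)


def _shift_slices(shape, axis: int, shift: int, source: bool):
    """Index tuples pairing each voxel with its neighbor at +shift on axis."""
    sl = [slice(None)] * len(shape)
    if (shift == 1) == source:
        sl[axis] = slice(None, -1)
    else:
        sl[axis] = slice(1, None)
    return tuple(sl)


# ---------------------------------------------------------------------------
# End-to-end structure segmentation
# ---------------------------------------------------------------------------

def _slice_object_mask(img: np.ndarray, params: SegmentationParams, spacing2d):
    m = band_mask(img, *params.hu_window, spacing=spacing2d)
    if params.smooth_size > 1:
        # majority filter: box-smooth the binary labels and re-threshold,
        # suppressing isolated noise pixels without moving HU levels into
        # the window (smoothing grey values first would blend air and soft
        # tissue across any intermediate window)
        sm = smooth(m.data.astype(float), params.smooth_size)
        m = BinaryMask((sm >= 0.5).astype(np.uint8), spacing=spacing2d)
    return remove_small_regions(m, spacing2d, params.min_region_area_cm2)


def _component_at(mask: np.ndarray, pixel, connectivity: int) -> np.ndarray:
    structure = _STRUCT8 if connectivity == 8 else None
    labels, _ = ndimage.label(mask, structure=structure)
    lab = labels[pixel]
    if lab == 0:
        return np.zeros_like(mask, dtype=bool)
    return labels == lab


def _segment_slice(img, seed_rc, params, spacing2d):
    """One slice of the pipeline; returns (path, filled, centroid) or None
    when the structure is absent on this slice."""
    m = _slice_object_mask(img, params, spacing2d)
    if not m.data.any():
        return None
    seed_rc = relocate_seed_outside(m, seed_rc)
    comp = _component_at(m.data, seed_rc, params.connectivity)
    if not comp.any():
        return None
    path = track_boundary(comp.astype(np.uint8), seed_rc)
    filled = fill_polygon_slice(np.asarray(path, dtype=float), comp.shape)
    rr, cc = np.nonzero(filled)
    centroid = (int(round(rr.mean())), int(round(cc.mean())))
    return path, filled, centroid


def segment_structure(
    volume: VoxelVolume, seed: SeedPoint, params: SegmentationParams
) -> SegmentationResult:
    """Trace one structure through the volume from a single seed.

    Starting at the seed slice, each slice is thresholded, cleaned, traced,
    and filled; the filled region's centroid seeds the neighboring slices in
    both stack directions.  Tracking stops in a direction when the structure
    vanishes (empty slice mask, or the traced region no longer overlaps the
    previous slice's region); a partial result is returned with a warning
    record in that case.

    Returns per-slice contours in mm plus the filled 3D mask; filling the
    returned contours reproduces the mask slice-by-slice exactly.
    """
    data = np.asarray(volume.data, dtype=float)
    nz, ny, nx = data.shape
    z0, r0, c0 = (int(v) for v in seed.position)
    if not (0 <= z0 < nz and 0 <= r0 < ny and 0 <= c0 < nx):
        raise OutOfBoundsError(f"seed {seed.position} outside volume {data.shape}")
    spacing2d = (volume.spacing[1], volume.spacing[2])
    warnings: list[str] = []

    first = _segment_slice(data[z0], (r0, c0), params, spacing2d)
    if first is None:
        raise NoObjectError(
            f"no structure found in the HU window on seed slice {z0}"
        )
    per_slice: dict[int, tuple[list, np.ndarray]] = {z0: (first[0], first[1])}

    for direction in (1, -1):
        prev_fill = first[1]
        seed_rc = first[2]
        z = z0 + direction
        while 0 <= z < nz:
            res = _segment_slice(data[z], seed_rc, params, spacing2d)
            if res is None:
                break
            path, filled, centroid = res
            if not np.any(filled & prev_fill):
                warnings.append(
                    f"structure lost continuity at slice {z}; stopped"
                )
                break
            per_slice[z] = (path, filled)
            prev_fill, seed_rc = filled, centroid
            z += direction

    # assemble outputs
    oz, oy, ox = volume.origin
    dz, dy, dx = volume.spacing
    cs = ContourSet("structure", slice_spacing_mm=dz)
    mask3d = np.zeros((nz, ny, nx), dtype=np.uint8)
    for z, (path, filled) in sorted(per_slice.items()):
        mask3d[z] = filled
        pts_px = np.asarray(path[:-1], dtype=float)  # drop closing duplicate
        pts_mm = np.column_stack(
            [oy + (pts_px[:, 0] + 0.5) * dy, ox + (pts_px[:, 1] + 0.5) * dx]
        )
        try:
            c = Contour(z, pts_mm, closed=True)
        except Exception:
            continue  # degenerate sliver (< 3 distinct boundary pixels)
        if params.decimate_percent > 0 and len(c) >= 4:
            from .contours import decimate as _decimate

            c = _decimate(c, params.decimate_percent)
            # keep mask consistent with the decimated contour
            rows = (c.points[:, 0] - oy) / dy - 0.5
            cols = (c.points[:, 1] - ox) / dx - 0.5
            mask3d[z] = fill_polygon_slice(
                np.column_stack([rows, cols]), (ny, nx)
            )
        cs.add(c)
    return SegmentationResult(
        contours=cs,
        mask=BinaryMask(mask3d, spacing=volume.spacing),
        warnings=warnings,
    )
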