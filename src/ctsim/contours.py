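"""Contour data model, metrics, decimation, and inter-slice interpolation.

A contour is an ordered list of (y, x) points in mm on one axial slice.
Metrics are the shoelace area (cm^2) and the polyline periphery (cm).
Decimation removes k% of the points by uniform stride.  Inter-slice
interpolation resamples two key contours into the same number of
equiangular sectors about their centroids, forms triangles between
corresponding sector points, and intersects the triangle sides with the
intermediate plane — which reduces to per-sector linear blending of the
matched points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw

from .errors import (
    DegenerateContourError,
    InvalidParameterError,
    OutOfBoundsError,
)
from .volume import BinaryMask, VoxelVolume

__all__ = [
    "Contour",
    "ContourSet",
    "contour_area",
    "contour_periphery",
    "decimate",
    "interpolate_contours",
    "contours_to_mask",
    "fill_polygon_slice",
]


@dataclass
class Contour:
    """Ordered (y, x) mm points on one slice; closed contours have >= 3
    distinct points and no consecutive duplicates (the closing edge from the
    last point back to the first is implicit)."""

    slice_index: int
    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("contour points must be (N, 2) (y, x) mm")
        if len(pts) >= 2:
            dup = np.all(np.isclose(pts[1:], pts[:-1]), axis=1)
            if np.any(dup):
                pts = pts[np.concatenate(([True], ~dup))]
        if self.closed:
            if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
            distinct = np.unique(np.round(pts, 9), axis=0)
            if len(distinct) < 3:
                raise DegenerateContourError(
                    "closed contour needs >= 3 distinct points"
                )
        elif len(pts) < 2:
            raise InvalidParameterError("open contour needs >= 2 points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def signed_area_mm2(self) -> float:
        """Shoelace signed area in mm^2; positive = counter-clockwise in
        (x, y) with y up (i.e. in the (y, x) plane as stored)."""
        y = self.points[:, 0]
        x = self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def oriented(self, counterclockwise: bool = True) -> "Contour":
        """Copy with winding normalized (reversed if needed)."""
        if not self.closed:
            return Contour(self.slice_index, self.points.copy(), closed=False)
        pos = self.signed_area_mm2() > 0
        pts = self.points if pos == counterclockwise else self.points[::-1]
        return Contour(self.slice_index, pts.copy(), closed=True)

    def centroid(self) -> np.ndarray:
        """Area centroid (y, x) mm of a closed contour."""
        if not self.closed:
            return self.points.mean(axis=0)
        y = self.points[:, 0]
        x = self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        if abs(a) < 1e-12:
            return self.points.mean(axis=0)
        cy = float(np.sum((y + yn) * cross) / (6.0 * a))
        cx = float(np.sum((x + xn) * cross) / (6.0 * a))
        return np.array([cy, cx])


@dataclass
class ContourSet:
    """Contours of one structure keyed by slice index, plus slice spacing."""

    name: str
    contours: dict[int, Contour] = field(default_factory=dict)
    slice_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.slice_spacing_mm <= 0:
            raise InvalidParameterError("slice spacing must be > 0")
        self.contours = dict(sorted(self.contours.items()))

    def add(self, contour: Contour) -> None:
        self.contours[contour.slice_index] = contour
        self.contours = dict(sorted(self.contours.items()))

    def slice_indices(self) -> list[int]:
        return list(self.contours)

    def to_json_dict(self) -> dict:
        return {
            "structure": self.name,
            "slice_spacing_mm": self.slice_spacing_mm,
            "contours": {
                str(k): c.points.tolist() for k, c in self.contours.items()
            },
        }

    @staticmethod
    def from_json_dict(d: dict) -> "ContourSet":
        cs = ContourSet(
            d["structure"], slice_spacing_mm=float(d.get("slice_spacing_mm", 1.0))
        )
        for k, pts in d.get("contours", {}).items():
            cs.add(Contour(int(k), np.asarray(pts, dtype=float)))
        return cs

    def save_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @staticmethod
    def load_json(path: str) -> "ContourSet":
        with open(path) as fh:
            return ContourSet.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def contour_area(c: Contour) -> float:
    """Absolute shoelace polygon area of a closed contour, in cm^2."""
    if not c.closed:
        raise DegenerateContourError("area requires a closed contour")
    return abs(c.signed_area_mm2()) / 100.0


def contour_periphery(c: Contour) -> float:
    """Polyline length (plus the closing segment when closed), in cm."""
    pts = c.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    if c.closed and len(pts) >= 2:
        seg += np.linalg.norm(pts[-1] - pts[0])
    return float(seg) / 10.0


# ---------------------------------------------------------------------------
# Decimation
# ---------------------------------------------------------------------------

def decimate(c: Contour, k_percent: float) -> Contour:
    """Remove k% of the points by uniform stride over the ordered sequence.

    Retains ``m = floor(N * (1 - k/100))`` points, always including the
    first; the result is a subsequence of the input in the original order.
    """
    if not 0 <= k_percent < 100:
        raise InvalidParameterError(f"k must be in [0, 100), got {k_percent}")
    n = len(c.points)
    if n < 4:
        raise InvalidParameterError("decimation needs a contour with >= 4 points")
    m = math.floor(n * (1.0 - k_percent / 100.0))
    if c.closed and m < 3:
        raise DegenerateContourError(
            f"decimation to {m} points would break the closed contour"
        )
    if m < 1:
        raise DegenerateContourError("decimation would remove every point")
    idx = np.floor(np.arange(m) * n / m).astype(int)
    return Contour(c.slice_index, c.points[idx], closed=c.closed)


# ---------------------------------------------------------------------------
# Inter-slice interpolation
# ---------------------------------------------------------------------------

def _resample_equiangular(c: Contour, sectors: int) -> np.ndarray:
    """Resample a closed contour to ``sectors`` points at equal angles about
    its centroid: point k is the farthest intersection of the ray at angle
    2*pi*k/sectors with the polygon."""
    ctr = c.centroid()
    pts = c.points - ctr
    if np.max(np.abs(pts)) < 1e-12 or abs(c.signed_area_mm2()) < 1e-12:
        raise DegenerateContourError("zero-area contour cannot be resampled")
    p0 = pts
    p1 = np.roll(pts, -1, axis=0)
    edge = p1 - p0  # (N, 2) in (y, x)
    out = np.empty((sectors, 2))
    for k in range(sectors):
        th = 2.0 * math.pi * k / sectors
        d = np.array([math.sin(th), math.cos(th)])  # (dy, dx)
        # solve r*d = p0 + s*edge  for each edge
        # solve r*d = p0 + s*edge for each edge (d=(dy,dx), edge=(ey,ex)):
        # s = (dy*p0x - dx*p0y) / (dx*ey - dy*ex)
        det = d[1] * edge[:, 0] - d[0] * edge[:, 1]
        ok = np.abs(det) > 1e-14
        s = np.full(len(p0), np.nan)
        r = np.full(len(p0), np.nan)
        s[ok] = (d[0] * p0[ok, 1] - d[1] * p0[ok, 0]) / det[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            r[ok] = np.where(
                np.abs(d[1]) > np.abs(d[0]),
                (p0[ok, 1] + s[ok] * edge[ok, 1]) / d[1],
                (p0[ok, 0] + s[ok] * edge[ok, 0]) / d[0],
            )
        hit = ok & (s >= -1e-12) & (s <= 1 + 1e-12) & np.isfinite(r) & (r > 1e-12)
        if not np.any(hit):
            raise DegenerateContourError(
                "contour is not star-shaped about its centroid"
            )
        rk = np.max(r[hit])
        out[k] = ctr + rk * d
    return out


def interpolate_contours(
    a: Contour, b: Contour, t: float, sectors: int = 64
) -> Contour:
    """Linearly interpolate between two key contours at fraction ``t``.

    Both contours are wound the same way, resampled into ``sectors``
    equiangular sectors about their centroids, and corresponding sector
    points are blended ``(1-t)*a + t*b`` — the intersection of the
    inter-contour triangle sides with the intermediate plane.  ``t=0``/
    ``t=1`` reproduce the resampled inputs.
    """
    if not (a.closed and b.closed):
        raise InvalidParameterError("interpolation requires closed contours")
    if not 0.0 <= t <= 1.0:
        raise InvalidParameterError(f"t must be in [0, 1], got {t}")
    if sectors < 3:
        raise InvalidParameterError("need at least 3 sectors")
    pa = _resample_equiangular(a.oriented(), sectors)
    pb = _resample_equiangular(b.oriented(), sectors)
    pts = (1.0 - t) * pa + t * pb
    zi = a.slice_index if t <= 0.5 else b.slice_index
    return Contour(zi, pts, closed=True)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _scanline_fill(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline fill: pixel centers (integer row/col in pixel
    coordinates) strictly inside the closed polygon ``pts`` (N, 2)."""
    out = np.zeros(shape, dtype=np.uint8)
    y0 = pts[:, 0]
    x0 = pts[:, 1]
    y1 = np.roll(y0, -1)
    x1 = np.roll(x0, -1)
    keep = y0 != y1
    y0, x0, y1, x1 = y0[keep], x0[keep], y1[keep], x1[keep]
    if len(y0) == 0:
        return out
    ylo = np.minimum(y0, y1)
    yhi = np.maximum(y0, y1)
    r_start = np.ceil(ylo).astype(int)
    r_stop = np.ceil(yhi).astype(int)  # half-open [ylo, yhi)
    counts = np.maximum(r_stop - r_start, 0)
    if counts.sum() == 0:
        return out
    edge_idx = np.repeat(np.arange(len(y0)), counts)
    rows = np.concatenate(
        [np.arange(a, b) for a, b in zip(r_start, r_stop) if b > a]
    )
    t = (rows - y0[edge_idx]) / (y1[edge_idx] - y0[edge_idx])
    xs = x0[edge_idx] + t * (x1[edge_idx] - x0[edge_idx])
    ok = (rows >= 0) & (rows < shape[0])
    rows, xs = rows[ok], xs[ok]
    order = np.lexsort((xs, rows))
    rows, xs = rows[order], xs[order]
    # crossings come in pairs per row (even-odd rule)
    starts = np.searchsorted(rows, np.arange(shape[0]), side="left")
    ends = np.searchsorted(rows, np.arange(shape[0]), side="right")
    for r in np.unique(rows):
        rx = xs[starts[r]:ends[r]]
        for a, b in zip(rx[0::2], rx[1::2]):
            c0 = max(0, int(np.ceil(a)))
            c1 = min(shape[1], int(np.ceil(b)))
            if c1 > c0:
                out[r, c0:c1] = 1
    return out


def fill_polygon_slice(
    points_px: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a closed polygon given in (row, col) *pixel* coordinates.

    A pixel is object if its center lies inside the polygon (even-odd
    scanline rule), or if it lies on the drawn outline connecting
    consecutive polygon points (rounded to the grid).  This is the fill
    convention the segmenter uses, so that filling a traced boundary
    reproduces the traced region.
    """
    pts = np.asarray(points_px, dtype=float)
    out = np.zeros(shape, dtype=np.uint8)
    if len(pts) < 3:
        ij = np.rint(pts).astype(int)
        ok = (
            (ij[:, 0] >= 0)
            & (ij[:, 0] < shape[0])
            & (ij[:, 1] >= 0)
            & (ij[:, 1] < shape[1])
        )
        out[ij[ok, 0], ij[ok, 1]] = 1
        return out
    out = _scanline_fill(pts, shape)
    verts = np.vstack([pts, pts[:1]])
    ij = np.rint(verts).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
    for k in range(len(ij) - 1):
        rr, cc = skdraw.line(ij[k, 0], ij[k, 1], ij[k + 1, 0], ij[k + 1, 1])
        out[rr, cc] = 1
    return out


def contours_to_mask(cs: ContourSet, template: VoxelVolume) -> BinaryMask:
    """Rasterize a contour set into a binary volume congruent with
    ``template`` (per-slice polygon fill by center inclusion)."""
    nz, ny, nx = template.shape
    dz, dy, dx = template.spacing
    oz, oy, ox = template.origin
    data = np.zeros((nz, ny, nx), dtype=np.uint8)
    for zi, c in cs.contours.items():
        if not 0 <= zi < nz:
            raise OutOfBoundsError(f"contour slice {zi} outside volume (nz={nz})")
        # mm -> pixel (voxel centers at origin + (i + 0.5) * spacing)
        rows = (c.points[:, 0] - oy) / dy - 0.5
        cols = (c.points[:, 1] - ox) / dx - 0.5
        if (
            rows.min() < -0.5
            or cols.min() < -0.5
            or rows.max() > ny - 0.5
            or cols.max() > nx - 0.5
        ):
            raise OutOfBoundsError(
                f"contour on slice {zi} extends outside the volume grid"
            )
        data[zi] = fill_polygon_slice(np.column_stack([rows, cols]), (ny, nx))
    return BinaryMask(data, spacing=template.spacing)
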