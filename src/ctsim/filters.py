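"""2D convolution, smoothing, Sobel edges, and threshold classification.

The convolution ``g = w (*) f`` with a K x K kernel (K odd) is the basis of
all slice filtering.  Smoothing is a box-mean low-pass filter; edges come
from the classic 3x3 Sobel operator pair; object/background classification
is the threshold rule ``I(i,j) >= T -> object (1)``, else background (0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .volume import BinaryMask

__all__ = [
    "Kernel",
    "convolve2d",
    "smooth",
    "sobel_edges",
    "threshold_mask",
    "band_mask",
    "histogram_threshold",
]

# classic integer Sobel pair; Gx responds to horizontal (column) steps
SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_GY = SOBEL_GX.T


@dataclass(frozen=True)
class Kernel:
    """A K x K convolution mask with K odd and finite weights."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("kernel must be square")
        if w.shape[0] % 2 == 0:
            raise InvalidParameterError(f"kernel size must be odd, got {w.shape[0]}")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("kernel weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @staticmethod
    def box(size: int) -> "Kernel":
        """Uniform mean kernel (all weights 1/size^2)."""
        if size < 1 or size % 2 == 0:
            raise InvalidParameterError(f"box kernel size must be odd, got {size}")
        return Kernel(np.full((size, size), 1.0 / size**2))

    @staticmethod
    def identity() -> "Kernel":
        return Kernel(np.array([[1.0]]))


def convolve2d(image: np.ndarray, kernel: Kernel, border: str = "reflect") -> np.ndarray:
    """True 2D convolution (kernel flipped) with same-shape output.

    ``border`` selects the out-of-image rule: ``reflect`` mirrors the image
    at its edge, ``zero`` pads with zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("image must be 2D")
    if not isinstance(kernel, Kernel):
        kernel = Kernel(np.asarray(kernel))
    if kernel.size > min(img.shape):
        raise InvalidParameterError(
            f"kernel size {kernel.size} exceeds image shape {img.shape}"
        )
    if border == "reflect":
        return ndimage.convolve(img, kernel.weights, mode="reflect")
    if border == "zero":
        return ndimage.convolve(img, kernel.weights, mode="constant", cval=0.0)
    raise InvalidParameterError(f"unknown border rule {border!r}")


def smooth(image: np.ndarray, kernel_size: int = 3, border: str = "reflect") -> np.ndarray:
    """Box-mean smoothing; ``kernel_size`` must be odd (1 is the identity)."""
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise InvalidParameterError(
            f"smoothing kernel size must be odd and >= 1, got {kernel_size}"
        )
    if kernel_size == 1:
        return np.asarray(image, dtype=float).copy()
    return convolve2d(image, Kernel.box(kernel_size), border=border)


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) from the 3x3 Sobel pair.

    Left unscaled (classic integer masks): a unit step yields interior
    edge magnitude 4.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise InvalidParameterError("image must be 2D and at least 3x3")
    gx = convolve2d(img, Kernel(SOBEL_GX))
    gy = convolve2d(img, Kernel(SOBEL_GY))
    return np.hypot(gx, gy)


def threshold_mask(image: np.ndarray, T: float, spacing=(1.0, 1.0)) -> BinaryMask:
    """Classify pixels: 1 (object) where I >= T, 0 (background) otherwise."""
    img = np.asarray(image)
    return BinaryMask((img >= T).astype(np.uint8), spacing=spacing)


def band_mask(image: np.ndarray, low: float, high: float, spacing=(1.0, 1.0)) -> BinaryMask:
    """Two-sided HU window: object where low <= I <= high.

    Composition of the one-sided threshold rule applied at ``low`` and at
    just above ``high``.
    """
    if not low < high:
        raise InvalidParameterError(f"window low must be < high, got ({low}, {high})")
    img = np.asarray(image)
    data = ((img >= low) & (img <= high)).astype(np.uint8)
    return BinaryMask(data, spacing=spacing)


def histogram_threshold(
    image: np.ndarray,
    hu_window: tuple[float, float],
    bins: int = 128,
    smooth_width: int = 5,
) -> float:
    """Pick a single threshold inside an HU window from the image histogram.

    The histogram of values falling in ``hu_window`` is box-smoothed and the
    interior minimum (the valley between tissue modes) is returned.  When the
    smoothed histogram has no interior minimum (unimodal or flat within the
    window) the window midpoint is the fallback.
    """
    low, high = float(hu_window[0]), float(hu_window[1])
    if not low < high:
        raise InvalidParameterError(f"empty HU window ({low}, {high})")
    img = np.asarray(image, dtype=float).ravel()
    inside = img[(img >= low) & (img <= high)]
    midpoint = 0.5 * (low + high)
    if inside.size < 2:
        return midpoint
    hist, edges = np.histogram(inside, bins=bins, range=(low, high))
    k = np.ones(smooth_width) / smooth_width
    sm = np.convolve(hist.astype(float), k, mode="same")
    interior = sm[1:-1]
    if interior.size == 0 or np.allclose(interior, interior[0]):
        return midpoint
    i = int(np.argmin(interior)) + 1
    # reject minima at the window border (no valley)
    if sm[i] >= sm[0] and sm[i] >= sm[-1]:
        return midpoint
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[i])
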