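"""Shared fixtures: small phantoms, random-blob masks, and test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from ctsim.phantoms import PhantomSpec, generate_thorax


@pytest.fixture(scope="session")
def thorax_small():
    """A reduced thorax phantom (48 x 96 x 96) for fast unit tests."""
    return generate_thorax(PhantomSpec.thorax(slices=48, matrix=96))


@pytest.fixture(scope="session")
def thorax_default():
    """The default thorax phantom (128 x 256 x 256), noiseless."""
    return generate_thorax(PhantomSpec.thorax())


def random_filled_blob(rng: np.random.Generator, shape=(24, 24), density=0.45):
    """A random filled single 4-connected component, or None if empty."""
    m = ndimage.binary_closing(rng.random(shape) < density)
    labels, n = ndimage.label(m)  # 4-connected
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = ndimage.binary_fill_holes(labels == counts.argmax())
    if comp.sum() < 3:
        return None
    return comp


def boundary_oracle(comp: np.ndarray) -> set:
    """Morphological boundary: object pixels minus the 4-erosion."""
    inner = ndimage.binary_erosion(comp)  # 4-connected structuring element
    return set(map(tuple, np.argwhere(comp & ~inner)))


def flood_fill_oracle(data: np.ndarray, seed, delta: float) -> np.ndarray:
    """Depth-first 6-connected flood fill accepting steps of |dv| <= delta."""
    acc = np.zeros(data.shape, dtype=bool)
    acc[seed] = True
    stack = [tuple(seed)]
    nbrs = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in nbrs:
            n = (z + dz, y + dy, x + dx)
            if not all(0 <= n[i] < data.shape[i] for i in range(3)):
                continue
            if acc[n]:
                continue
            if abs(data[n] - data[z, y, x]) <= delta:
                acc[n] = True
                stack.append(n)
    return acc


def brute_convolve(image: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Nested-loop true convolution with zero padding (reference oracle)."""
    kh, kw = weights.shape
    rh, rw = kh // 2, kw // 2
    out = np.zeros_like(image, dtype=float)
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    ii = i + rh - a
                    jj = j + rw - b
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += weights[a, b] * image[ii, jj]
            out[i, j] = acc
    return out
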