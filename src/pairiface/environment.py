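"""Decayed-weight kernels and same-shape 2-D convolution of feature matrices.

Each base feature matrix is convolved with a small square kernel whose
weights fall off linearly with Chebyshev ring distance from the center, so
every residue pair's "environment" value reflects its neighborhood on the
pair grid. Output size equals input size (zero padding outside the matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .features import ALL_FEATURES, BASE_FEATURES, FeatureStack, minmax_scale

VALID_SIZES = (3, 5, 7)


@dataclass(frozen=True)
class Kernel:
    """Square ring-decay kernel.

    The center weight is 1 before normalization and the weight of a cell at
    Chebyshev distance r from the center is ``1 - r * decay``. Normalized
    kernels divide by the weight sum (averaging convolution).
    """

    size: int
    decay: float
    normalized: bool
    weights: np.ndarray

    def spec(self) -> dict:
        return {"size": self.size, "decay": self.decay, "normalized": self.normalized}


def make_kernel(size: int, decay: float, normalized: bool = True) -> Kernel:
    """Build a ring-decay kernel.

    Parameters
    ----------
    size
        Odd window size, one of 3, 5 or 7.
    decay
        Per-ring linear weight decrease, in [0, 0.25]. Must leave every
        weight strictly positive.
    normalized
        Divide weights by their sum so convolution averages.
    """
    if size not in VALID_SIZES:
        raise ValueError(f"kernel size must be one of {VALID_SIZES}, got {size}")
    if not 0 <= decay <= 0.25:
        raise ValueError(f"decay must lie in [0, 0.25], got {decay}")
    half = size // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    ring = np.maximum(np.abs(yy), np.abs(xx))
    weights = 1.0 - ring * decay
    if (weights <= 0).any():
        raise ValueError(f"decay {decay} drives outer-ring weights to <= 0")
    if normalized:
        weights = weights / weights.sum()
    return Kernel(size=size, decay=decay, normalized=normalized, weights=weights)


def convolve_same(matrix: np.ndarray, kernel: Kernel) -> np.ndarray:
    """2-D cross-correlation with zero padding; output shape = input shape.

    Ring-decay kernels are symmetric under 180-degree rotation, so
    cross-correlation and flipped-kernel convolution coincide.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("input must be a non-empty 2-D matrix")
    return correlate(m, kernel.weights, mode="constant", cval=0.0)


def derive_env_stack(stack: FeatureStack, kernel: Kernel) -> FeatureStack:
    """Extend a 9-feature base stack with its 9 convolved counterparts.

    The derived matrices are named with an ``E`` prefix (ECMI, ERSA, ...)
    and each is min-max rescaled to [0, 1] after convolution. Returns the
    full 18-feature stack in canonical order.
    """
    if tuple(stack.feature_order) != BASE_FEATURES:
        raise ValueError(
            f"expected the 9 base features {BASE_FEATURES}, "
            f"got {tuple(stack.feature_order)}"
        )
    mats = dict(stack.matrices)
    for name in BASE_FEATURES:
        mats["E" + name] = minmax_scale(convolve_same(stack[name], kernel))
    return FeatureStack(matrices=mats, feature_order=ALL_FEATURES)
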