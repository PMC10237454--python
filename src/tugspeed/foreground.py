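"""Silhouette extraction: background subtraction, denoising, centroid.

Each video frame is converted to grayscale, differenced against a static
background frame, thresholded (default tau = 50 grey levels), cleaned with
a 5x5 binary median filter, and reduced to the geometric centroid of the
foreground pixels (unit mass per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tugspeed.errors import InvalidInputError, InvalidParameterError

__all__ = [
    "PixelCentroid",
    "to_grayscale",
    "subtract_and_threshold",
    "median_denoise",
    "silhouette_centroid",
    "largest_component",
]

DEFAULT_TAU = 50.0
DEFAULT_MEDIAN_KERNEL = 5

# ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PixelCentroid:
    """Sub-pixel silhouette centroid with a validity flag.

    ``valid`` is False when the mask contained no foreground pixels, in
    which case ``u_px``/``v_px`` are NaN.
    """

    u_px: float
    v_px: float
    valid: bool
    n_pixels: int


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to float grayscale (BT.601 luminance).

    2-D input is assumed to already be grayscale and is passed through as
    float64.  Any other channel count raises :class:`InvalidInputError`.
    """
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr.astype(np.float64) @ _LUMA
    raise InvalidInputError(f"expected HxW or HxWx3 frame, got shape {arr.shape}")


def subtract_and_threshold(
    frame: np.ndarray, background: np.ndarray, tau: float = DEFAULT_TAU
) -> np.ndarray:
    """Foreground mask: absolute grayscale difference strictly above tau."""
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise InvalidInputError(
            f"frame shape {frame.shape} does not match background {background.shape}"
        )
    if tau < 0:
        raise InvalidParameterError(f"tau must be >= 0, got {tau}")
    return np.abs(frame - background) > tau


def median_denoise(mask: np.ndarray, kernel: int = DEFAULT_MEDIAN_KERNEL) -> np.ndarray:
    """Binary median filter over a kernel x kernel neighbourhood.

    For a binary image the median equals the majority vote, so this is
    computed with a box sum, which is much faster than a rank filter and
    bit-identical to it for odd kernels.  Borders are edge-replicated.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise InvalidParameterError(f"kernel must be odd and >= 1, got {kernel}")
    mask = np.asarray(mask, dtype=bool)
    if kernel == 1:
        return mask.copy()
    frac = ndimage.uniform_filter(mask.astype(np.float64), size=kernel, mode="nearest")
    return frac > 0.5


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Off by default in the pipeline (the whole-mask centroid is used);
    available for noisy inputs.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def silhouette_centroid(mask: np.ndarray) -> PixelCentroid:
    """Geometric centre of mass of the foreground pixels (unit mass each).

    An empty mask yields ``valid=False`` rather than an exception; the
    caller interpolates such frames later.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n == 0:
        return PixelCentroid(u_px=float("nan"), v_px=float("nan"), valid=False, n_pixels=0)
    return PixelCentroid(
        u_px=float(cols.mean()), v_px=float(rows.mean()), valid=True, n_pixels=int(n)
    )
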