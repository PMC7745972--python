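"""Chroma-key background removal for blue-keyed plant images.

A uniformly blue keying background sits far down the CIELAB b axis (the
blue-yellow opponent axis), while plant matter and soil sit high on it, so
a single threshold on the b channel separates foreground from background.
Morphological cleanup smooths the thresholded mask; the keyed-out background
can then be replaced by any application-specific backdrop.  When the camera
repositions precisely, background subtraction against a plant-free capture
from the identical pose is available as a second keying route.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import color, morphology

__all__ = [
    "b_channel",
    "threshold_mask",
    "otsu_threshold",
    "cleanup",
    "replace_background",
    "background_subtract",
    "SegmentationError",
]

CLEANUP_OPS = ("dilate", "fill_holes", "erode", "blur")

#: Default cleanup recipe: close small gaps, fill interior holes, restore
#: the outline, then soften jagged edges.
DEFAULT_CLEANUP: list[tuple[str, float]] = [
    ("dilate", 3),
    ("fill_holes", 0),
    ("erode", 3),
    ("blur", 1.0),
]


class SegmentationError(ValueError):
    pass


def _require_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise SegmentationError(f"expected an H x W x 3 raster, got shape {image.shape}")


def b_channel(image: np.ndarray) -> np.ndarray:
    """CIELAB b axis of an 8-bit RGB raster, rescaled to uint8.

    Low values are blue, high values yellow; the achromatic axis sits near
    128.  The rescaling is the conventional 8-bit encoding b + 128.
    """
    _require_rgb(image)
    lab = color.rgb2lab(np.asarray(image, dtype=np.uint8))
    return np.clip(np.round(lab[..., 2] + 128.0), 0, 255).astype(np.uint8)


def threshold_mask(b: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask: pixels with b < threshold become background (0), else 1."""
    return (np.asarray(b) >= threshold).astype(np.uint8)


def otsu_threshold(b: np.ndarray) -> float:
    """Automatic threshold on the b channel (Otsu's criterion).

    Otsu separates at "strictly greater", while :func:`threshold_mask`
    keeps ``b >= threshold``; the returned level is shifted by half a level
    so the two conventions agree on integer-valued channels.
    """
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(b))) + 0.5


def cleanup(mask: np.ndarray, ops: list[tuple[str, float]] | None = None) -> np.ndarray:
    """Apply morphological operations in order; each op is (name, size).

    Supported: ``dilate``/``erode`` (square structuring element of the given
    side), ``fill_holes`` (size ignored), ``blur`` (Gaussian of the given
    sigma followed by re-binarization at 0.5).
    """
    out = np.asarray(mask).astype(bool)
    for name, size in ops if ops is not None else []:
        if name == "dilate":
            out = morphology.dilation(out, morphology.footprint_rectangle((int(size), int(size))))
        elif name == "erode":
            out = morphology.erosion(out, morphology.footprint_rectangle((int(size), int(size))))
        elif name == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        elif name == "blur":
            out = ndimage.gaussian_filter(out.astype(float), sigma=float(size)) >= 0.5
        else:
            raise SegmentationError(f"unknown cleanup op {name!r}")
    return out.astype(np.uint8)


def replace_background(image: np.ndarray, mask: np.ndarray, new_background: np.ndarray) -> np.ndarray:
    """Composite: foreground pixels from ``image``, the rest from ``new_background``."""
    img = np.asarray(image)
    bg = np.asarray(new_background)
    m = np.asarray(mask).astype(bool)
    if img.shape != bg.shape or m.shape != img.shape[:2]:
        raise SegmentationError("image, mask and background dimensions must match")
    return np.where(m[..., None], img, bg)


def background_subtract(image: np.ndarray, background_only: np.ndarray, tolerance: int = 0) -> np.ndarray:
    """Foreground mask by differencing against a plant-free capture of the same pose.

    A pixel is foreground when its maximum per-channel absolute difference
    exceeds ``tolerance`` levels (use a few levels for JPEG inputs, 0 for
    lossless rasters).
    """
    img = np.asarray(image)
    bg = np.asarray(background_only)
    if img.shape != bg.shape:
        raise SegmentationError("image and background dimensions must match")
    diff = np.abs(img.astype(np.int16) - bg.astype(np.int16))
    if diff.ndim == 3:
        diff = diff.max(axis=2)
    return (diff > tolerance).astype(np.uint8)
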