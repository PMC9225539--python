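"""Pre-segmentation image conditioning.

Three steps precede boundary extraction: a light morphological smoothing
(grayscale closing) that removes dark speckle, a local window-based
contrast enhancement that stretches each pixel against its neighborhood
min/max, and a lumen-intensity standardization that fills the segmented
lumen with the mean wall intensity so the inner edge no longer attracts
the outer contour.  Features are always computed from the original,
non-denoised image; these operators feed the segmentation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .imaging import GrayImage

__all__ = ["ContrastConfig", "morph_smooth", "enhance_contrast", "standardize_lumen", "wall_ring_from_inner"]


@dataclass(frozen=True)
class ContrastConfig:
    """Local contrast-stretch settings: odd window size (default 9 x 9)."""

    window: int = 9

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")


def morph_smooth(image: GrayImage, radius: int = 1) -> GrayImage:
    """Grayscale closing (dilation then erosion) with a disk element.

    Fills dark spots smaller than the disk; idempotent on constants.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(image.shape) // 2:
        raise ValueError(f"radius {radius} too large for image shape {image.shape}")
    footprint = disk(radius)
    dilated = ndimage.grey_dilation(image.pixels, footprint=footprint)
    closed = ndimage.grey_erosion(dilated, footprint=footprint)
    return GrayImage(closed, image.spacing)


def enhance_contrast(image: GrayImage, cfg: ContrastConfig = ContrastConfig()) -> GrayImage:
    """Window-based local contrast stretch.

    Per pixel: ``In = (Ii - M1) / (M2 - M1) * Mx`` with M1/M2 the
    neighborhood minimum/maximum inside the (truncated-at-borders) window
    and Mx the global maximum of the input image.  Where the window is
    flat (M1 == M2) the original intensity is kept.
    """
    px = image.pixels.astype(np.float64)
    w = cfg.window
    # +/-inf padding == window truncated at the image borders
    m1 = ndimage.minimum_filter(px, size=w, mode="constant", cval=np.inf)
    m2 = ndimage.maximum_filter(px, size=w, mode="constant", cval=-np.inf)
    mx = float(px.max())
    flat = m2 == m1
    out = np.where(flat, px, (px - m1) / np.where(flat, 1.0, m2 - m1) * mx)
    return GrayImage(out, image.spacing)


def wall_ring_from_inner(inner_mask: np.ndarray, width_px: int = 3) -> np.ndarray:
    """Ring just outside the inner contour, used to sample wall intensity
    before the outer boundary exists: dilation of the inner mask by
    ``width_px`` minus the inner mask itself."""
    inner = np.asarray(inner_mask, dtype=bool)
    dilated = ndimage.binary_dilation(inner, structure=disk(1), iterations=width_px)
    return dilated & ~inner


def standardize_lumen(image: GrayImage, inner_mask: np.ndarray, wall_ring_mask: np.ndarray) -> GrayImage:
    """Replace every lumen pixel by the mean intensity over the wall ring.

    With the bright urine signal flattened to the wall level, the outer
    level set no longer sees the inner boundary.  An empty inner mask
    leaves the image unchanged; an empty ring is a degenerate-region error.
    """
    inner = np.asarray(inner_mask, dtype=bool)
    ring = np.asarray(wall_ring_mask, dtype=bool)
    if inner.shape != image.shape or ring.shape != image.shape:
        raise ValueError("mask shapes must match the image")
    if not inner.any():
        return GrayImage(image.pixels.copy(), image.spacing)
    if not ring.any():
        raise ValueError("wall ring mask is empty; cannot estimate wall intensity")
    out = image.pixels.astype(np.float64).copy()
    out[inner] = float(image.pixels[ring].mean())
    return GrayImage(out, image.spacing)
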