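"""Image standardization ahead of texture analysis.

Ultrasound acquisitions vary in spatial resolution and gain, so frequency
features (cycles/mm) and amplitude features are only comparable after
resampling every image to a common pixel density and linearly rescaling
intensities against two anatomical references (blood, which should be
nearly black, and the adventitia, which should be bright).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .amfm import DEFAULT_PIXEL_DENSITY

__all__ = [
    "standardize_resolution",
    "normalize_intensity",
    "extract_roi",
    "BLOOD_TARGET",
    "ADVENTITIA_TARGET",
]

# target gray levels: midpoints of the reference ranges 0-5 (blood) and
# 180-190 (adventitia)
BLOOD_TARGET = 2.5
ADVENTITIA_TARGET = 185.0

ROI_LENGTH = 160  # pixels, i.e. 9.6 mm at 16.66 pixels/mm


def standardize_resolution(
    image: np.ndarray,
    pixel_density: float,
    target_density: float = DEFAULT_PIXEL_DENSITY,
) -> np.ndarray:
    """Bicubic resampling to a standard pixel density (pixels/mm)."""
    if pixel_density is None or pixel_density <= 0:
        raise ValueError("pixel_density must be known and > 0")
    img = np.asarray(image, dtype=float)
    factor = target_density / pixel_density
    if abs(factor - 1.0) < 1e-9:
        return img.copy()
    return ndimage.zoom(img, factor, order=3, mode="reflect", grid_mode=True)


def normalize_intensity(
    image: np.ndarray,
    blood_median: float,
    adventitia_median: float,
    targets: tuple[float, float] = (BLOOD_TARGET, ADVENTITIA_TARGET),
    out_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Linear intensity rescaling pinned to blood and adventitia medians.

    The affine map sends ``blood_median -> targets[0]`` and
    ``adventitia_median -> targets[1]``, then clips to ``out_range``.
    """
    if adventitia_median <= blood_median:
        raise ValueError("adventitia median must exceed blood median")
    img = np.asarray(image, dtype=float)
    slope = (targets[1] - targets[0]) / (adventitia_median - blood_median)
    out = targets[0] + slope * (img - blood_median)
    return np.clip(out, out_range[0], out_range[1])


def extract_roi(mask: np.ndarray, length: int = ROI_LENGTH) -> np.ndarray:
    """Restrict a segmentation mask to a fixed-length column window.

    The window of ``length`` columns is centered on the mask's column
    centroid (nearest integer, ties rounded down), so every image
    contributes a region of identical physical length.  Raises if the mask's
    horizontal extent is shorter than ``length``.
    """
    m = np.asarray(mask, dtype=bool)
    cols = np.where(m.any(axis=0))[0]
    if cols.size == 0:
        raise ValueError("empty mask")
    extent = cols[-1] - cols[0] + 1
    if extent < length:
        raise ValueError(
            f"mask horizontal extent is {extent} px, need at least {length} px"
        )
    centroid = float(np.nonzero(m)[1].mean())
    # window start = centroid - (length-1)/2, rounded to nearest (ties down)
    start = int(np.ceil(centroid - (length - 1) / 2.0 - 0.5))
    start = min(max(start, 0), m.shape[1] - length)
    out = np.zeros_like(m)
    out[:, start : start + length] = m[:, start : start + length]
    return out
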