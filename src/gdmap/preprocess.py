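"""Per-slice noise filtering of T1 maps and anatomy (ROI) mask construction.

The noise filter replaces each voxel by the median of itself and its four
in-plane edge neighbors (a plus-shaped, 5-element neighborhood), applied
slice by slice so it never mixes values across the 2 mm slice gap.  A voxel
carrying contrast in isolation is thereby replaced by the median of its
surroundings — the intended behavior: a single bright/dark voxel is more
likely noise than signal at this SNR.

NA voxels are excluded from every median set; a voxel whose whole 5-set is
NA stays NA.  Image borders use edge replication so the filter does not
shrink anatomy at the field-of-view edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .io_model import BinaryMask, ImageVolume, T1Map

__all__ = ["FilterSpec", "median_filter_t1", "make_roi_mask"]


@dataclass(frozen=True)
class FilterSpec:
    """Plus-shaped in-plane median filter: center + 4 edge neighbors."""

    per_slice: bool = True
    boundary: str = "replicate"


def _shifted_stack(sl: np.ndarray) -> np.ndarray:
    """Stack the 5-neighborhood of a 2D slice with edge replication: (5, r, c)."""
    p = np.pad(sl, 1, mode="edge")
    return np.stack(
        [
            p[1:-1, 1:-1],  # center
            p[:-2, 1:-1],  # up
            p[2:, 1:-1],  # down
            p[1:-1, :-2],  # left
            p[1:-1, 2:],  # right
        ]
    )


def median_filter_t1(t1_map: T1Map, spec: FilterSpec = FilterSpec()) -> T1Map:
    """Apply the plus-shaped median filter slice-wise, honoring the NA mask.

    NA voxels stay NA (no value is invented for a voxel whose own fit
    failed) and are excluded from their neighbors' median sets.
    """
    src = t1_map.t1.astype(float).copy()
    src[t1_map.na_mask] = np.nan
    out = np.empty_like(src)
    import warnings

    for z in range(src.shape[2]):
        stack = _shifted_stack(src[:, :, z])
        with warnings.catch_warnings():
            # all-NA neighborhoods are expected (background); they stay NA
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, :, z] = np.nanmedian(stack, axis=0)
    out[t1_map.na_mask] = np.nan
    na = ~np.isfinite(out)
    out[na] = np.nan
    return T1Map(
        t1=out,
        na_mask=na,
        fit_quality=t1_map.fit_quality,
        spacing=t1_map.spacing,
        origin=t1_map.origin,
    )


def _drop_small_components(binary: np.ndarray, min_px: int) -> np.ndarray:
    """Remove 2D connected components strictly smaller than ``min_px``."""
    labels, n = ndimage.label(binary)
    if n == 0:
        return binary
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def make_roi_mask(
    t1w: ImageVolume,
    min_px: int = 100,
    selem_size: int = 3,
    open_before_threshold: bool = True,
) -> BinaryMask:
    """Build the anatomy mask from a T1-weighted volume, slice by slice.

    Per slice: greyscale morphological opening, data-driven (Otsu) binary
    threshold, hole filling, removal of connected groupings smaller than
    ``min_px`` pixels, then binary closing.  A component of exactly
    ``min_px`` pixels survives.  Slices with no foreground yield an empty
    slice mask; an entirely empty result is returned with a warning rather
    than raised.

    ``open_before_threshold`` selects whether the greyscale opening precedes
    the threshold (default) or a binary opening follows it.
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    footprint = np.ones((selem_size, selem_size), dtype=bool)
    data = np.asarray(t1w.data, dtype=float)
    mask = np.zeros(data.shape, dtype=bool)
    for z in range(data.shape[2]):
        sl = data[:, :, z]
        if open_before_threshold:
            sl = morphology.opening(sl, footprint)
        if np.ptp(sl) == 0:
            continue  # constant slice: no data-driven foreground
        level = threshold_otsu(sl)
        binary = sl > level
        if not open_before_threshold:
            binary = morphology.opening(binary, footprint)
        binary = ndimage.binary_fill_holes(binary)
        binary = _drop_small_components(binary, min_px)
        binary = morphology.closing(binary, footprint)
        mask[:, :, z] = binary
    if not mask.any():
        import warnings

        warnings.warn("ROI mask is empty on every slice", stacklevel=2)
    return BinaryMask(mask, t1w.spacing, t1w.origin)
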