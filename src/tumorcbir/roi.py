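"""Tumor-region augmentation.

The ROI is the tumor mask dilated by a disk-shaped structuring element of
radius ``R`` pixels, so that peri-tumoral tissue (which carries diagnostic
context: meningiomas abut the skull, gliomas involve white matter, pituitary
tumors sit near the sphenoid sinus) contributes local features.  A pixel is
in the ROI iff its Euclidean distance to some tumor pixel is <= R; the result
is clipped to the image bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import ValidationError

__all__ = ["RoiMask", "disk_footprint", "augment_tumor_region"]


@dataclass(frozen=True)
class RoiMask:
    """Augmented ROI: a boolean raster plus the dilation radius that made it."""

    mask: np.ndarray
    radius_used: int

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def disk_footprint(R: int) -> np.ndarray:
    """Disk structuring element: offsets (di, dj) with di**2 + dj**2 <= R**2."""
    if R < 0:
        raise ValueError("R must be >= 0")
    r = int(R)
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    return (di * di + dj * dj) <= R * R


def augment_tumor_region(tumor_mask: np.ndarray, R: int) -> RoiMask:
    """Dilate the tumor mask by a radius-``R`` Euclidean disk.

    ``R=0`` returns the tumor mask itself (no augmentation).  Raises
    :class:`ValidationError` for an empty mask and ``ValueError`` for R < 0.
    """
    mask = np.asarray(tumor_mask).astype(bool)
    if mask.ndim != 2:
        raise ValidationError("tumor mask must be 2-D")
    if not mask.any():
        raise ValidationError("tumor mask has no foreground pixel")
    if R < 0:
        raise ValueError("dilation radius R must be >= 0")
    if R == 0:
        return RoiMask(mask=mask.copy(), radius_used=0)
    out = ndimage.binary_dilation(mask, structure=disk_footprint(R))
    return RoiMask(mask=out, radius_used=int(R))
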