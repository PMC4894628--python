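"""Adaptive spatial pooling by intensity order.

The ROI's pixels are sorted by intensity (ascending, ties broken by
row-major pixel index for reproducibility) and split into N consecutive
blocks of near-equal size: with |ROI| = q*N + r, the first r blocks get
q+1 pixels.  Unlike a fixed spatial-pyramid grid, this partition adapts to
ROIs of arbitrary shape while still encoding joint spatial/intensity
structure: each subregion is a coherent intensity stratum of the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import RoiMask

__all__ = ["Partition", "divide_by_intensity_order"]


@dataclass(frozen=True)
class Partition:
    """Ordered subregions (lowest to highest intensity bin) of an ROI.

    Each subregion is an (m, 2) int array of (row, col) pixel coordinates.
    """

    subregions: tuple[np.ndarray, ...]
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.subregions)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.subregions)


def divide_by_intensity_order(
    image: np.ndarray, roi: RoiMask | np.ndarray, N: int
) -> Partition:
    """Split the ROI into ``N`` equal-size intensity-ordered subregions."""
    if N < 1:
        raise ValueError("N must be >= 1")
    image = np.asarray(image, dtype=float)
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi).astype(bool)
    if mask.shape != image.shape:
        raise ValueError("ROI mask shape does not match image shape")
    rows, cols = np.nonzero(mask)  # row-major order
    n_pix = rows.size
    if n_pix == 0:
        raise ValueError("ROI is empty")
    if n_pix < N:
        raise ValueError(f"too few ROI pixels ({n_pix}) for N={N} subregions")
    order = np.argsort(image[rows, cols], kind="stable")  # ties keep raster order
    coords = np.column_stack([rows, cols])[order]
    q, r = divmod(n_pix, N)
    sizes = [q + 1] * r + [q] * (N - r)
    bounds = np.cumsum([0] + sizes)
    subregions = tuple(coords[bounds[i] : bounds[i + 1]] for i in range(N))
    return Partition(subregions=subregions, source_shape=image.shape)
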