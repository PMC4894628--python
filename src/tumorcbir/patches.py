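"""Raw-patch local features and PCA reduction.

Local features are vectorized W x W raw intensity patches centered at every
subregion pixel (gradient-based descriptors such as SIFT carry little
information in homogeneous MRI tissue, so raw intensities are used).
Windows that extend past the image border are completed by edge replication
so every pixel yields a descriptor.  Before encoding, descriptors are
decorrelated and reduced by PCA, keeping the smallest dimensionality whose
cumulative explained variance reaches the configured target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PatchSet", "PcaModel", "extract_patches", "fit_pca", "apply_pca"]


@dataclass
class PatchSet:
    """T descriptors of dimension d (one row per subregion pixel)."""

    descriptors: np.ndarray
    origin: int = 0

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.descriptors.ndim != 2:
            raise ValueError("descriptors must be a 2-D matrix")

    @property
    def T(self) -> int:
        return self.descriptors.shape[0]

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]


@dataclass
class PcaModel:
    """Linear reduction x -> (x - mean) @ components.T with orthonormal rows."""

    mean: np.ndarray
    components: np.ndarray
    explained_fraction: float

    @property
    def d(self) -> int:
        return self.components.shape[0]


def extract_patches(
    image: np.ndarray, pixel_set: np.ndarray, W: int, stride: int = 1
) -> PatchSet:
    """Vectorized W x W windows centered at each pixel of ``pixel_set``.

    ``pixel_set`` is an (m, 2) array of (row, col) coordinates; border
    windows are completed by edge replication, so the row count always
    equals the number of (stride-subsampled) pixels.  ``stride`` keeps every
    stride-th pixel of the set (in its given order) for faster encoding.
    """
    if W < 3 or W % 2 == 0:
        raise ValueError("patch side W must be an odd integer >= 3")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    image = np.asarray(image, dtype=float)
    coords = np.asarray(pixel_set)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("pixel_set must be an (m, 2) array of (row, col)")
    coords = coords[::stride]
    h = W // 2
    padded = np.pad(image, h, mode="edge")
    # all W*W offsets relative to the padded top-left corner of each window
    rows = coords[:, 0][:, None, None] + np.arange(W)[None, :, None]
    cols = coords[:, 1][:, None, None] + np.arange(W)[None, None, :]
    windows = padded[rows, cols]  # (m, W, W), row-major vectorization below
    return PatchSet(descriptors=windows.reshape(len(coords), W * W))


def fit_pca(sample: np.ndarray, variance_target: float) -> PcaModel:
    """Fit PCA on a descriptor sample; keep the fewest components reaching
    ``variance_target`` cumulative explained variance.

    Component signs are fixed so each row's largest-magnitude entry is
    positive (reproducible across BLAS backends).  A zero-variance sample
    degenerates to d=1 with a warning.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2:
        raise ValueError("sample must be a 2-D matrix")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if sample.shape[0] < sample.shape[1]:
        raise ValueError(
            f"need at least {sample.shape[1]} sample rows, got {sample.shape[0]}"
        )
    total_var = sample.var(axis=0).sum()
    if total_var <= 0:
        warnings.warn("degenerate (zero-variance) PCA sample; keeping d=1")
        comp = np.zeros((1, sample.shape[1]))
        comp[0, 0] = 1.0
        return PcaModel(mean=sample.mean(axis=0), components=comp, explained_fraction=1.0)
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(sample)
    cum = np.cumsum(pca.explained_variance_ratio_)
    # smallest d with cumulative explained variance >= target (1.0 -> full rank)
    reached = np.nonzero(cum >= variance_target - 1e-12)[0]
    d = int(reached[0]) + 1 if reached.size else len(cum)
    components = pca.components_[:d].copy()
    flip = np.sign(components[np.arange(d), np.abs(components).argmax(axis=1)])
    components *= flip[:, None]
    return PcaModel(
        mean=pca.mean_, components=components, explained_fraction=float(cum[d - 1])
    )


def apply_pca(model: PcaModel, patches: PatchSet) -> PatchSet:
    """Project descriptors: (x - mean) @ components.T; row count unchanged."""
    X = patches.descriptors
    if X.shape[1] != model.components.shape[1]:
        raise ValueError(
            f"descriptor dim {X.shape[1]} != model dim {model.components.shape[1]}"
        )
    return PatchSet(
        descriptors=(X - model.mean) @ model.components.T, origin=patches.origin
    )
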