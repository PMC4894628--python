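"""Synthetic phantom cohorts for end-to-end testing of the retrieval pipeline.

Each phantom slice is a small grayscale image containing an irregular
simply-connected "tumor" (a randomly deformed star-shaped disk) whose
interior carries class-specific smoothed-noise texture, surrounded by a
peri-tumoral annulus of class-specific mean intensity and width (so that
augmenting the ROI beyond the mask genuinely adds class information, the
way peri-tumoral tissue does for real brain tumors), on a noisy background.
Patients own several slices of one class and share a small random intensity
offset, which makes patient-stratified cross-validation meaningfully harder
than slice-random splits.

A single ``separability`` scalar multiplies every between-class parameter
difference: at 0 all classes are drawn from one distribution (labels carry
no image information); at 1 classes are well separated.  All randomness
flows from one seeded generator in a fixed order, so a seed fully
determines the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon

from .data import Cohort, TumorCase, ValidationError
from .roi import disk_footprint

__all__ = ["PhantomParams", "generate_cohort", "perturb_mask"]


@dataclass(frozen=True)
class PhantomParams:
    n_patients: int = 48
    slices_per_patient: tuple[int, int] = (2, 3)  # inclusive range
    n_classes: int = 3
    image_size: int = 64
    tumor_radius_range: tuple[float, float] = (8.0, 13.0)
    #: base (mean intensity, noise sd, smoothing length px) of tumor texture
    texture_base: tuple[float, float, float] = (0.55, 0.18, 1.5)
    #: base (mean intensity, width px) of the peri-tumoral annulus
    context_base: tuple[float, float] = (0.45, 4.0)
    background_mean: float = 0.30
    background_noise_sd: float = 0.05
    patient_offset_sd: float = 0.03
    #: scales every between-class parameter difference; 0 = identical classes
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_patients < self.n_classes:
            raise ValueError("need at least one patient per class")
        lo, hi = self.slices_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("slices_per_patient must be a positive inclusive range")
        if self.tumor_radius_range[0] <= 0:
            raise ValueError("tumor radii must be positive")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")


def _class_params(p: PhantomParams) -> list[dict]:
    """Per-class generative parameters; identical across classes iff sep=0."""
    out = []
    for c in range(p.n_classes):
        # symmetric offsets in [-1/2, 1/2]
        delta = (c - (p.n_classes - 1) / 2) / max(p.n_classes - 1, 1)
        s = p.separability
        tex_mean, tex_sd, tex_len = p.texture_base
        ctx_mean, ctx_width = p.context_base
        out.append(
            dict(
                tex_mean=tex_mean + 0.25 * s * delta,
                tex_sd=tex_sd * (1.0 + 0.4 * s * delta),
                tex_len=tex_len * (1.0 + 0.8 * s * (delta + 0.5)),
                ctx_mean=ctx_mean + 0.35 * s * delta,
                ctx_width=max(1, round(ctx_width + 3.0 * s * delta)),
            )
        )
    return out


def _tumor_mask(rng: np.random.Generator, p: PhantomParams) -> np.ndarray:
    """Irregular star-shaped tumor: a disk with low-order radial deformation."""
    r_lo, r_hi = p.tumor_radius_range
    max_ctx = _class_params(p)[-1]["ctx_width"]
    margin = r_hi * 1.3 + max_ctx + 2
    if 2 * margin >= p.image_size:
        raise ValueError(
            f"tumor plus context (margin {margin:.0f}px) cannot fit in a "
            f"{p.image_size}px image"
        )
    r0 = rng.uniform(r_lo, r_hi)
    center = rng.uniform(margin, p.image_size - margin, size=2)
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    radius = np.full_like(theta, r0)
    for m in (2, 3, 4):  # low harmonics keep the boundary star-shaped
        radius *= 1.0 + rng.uniform(-0.08, 0.08) * np.cos(
            m * theta + rng.uniform(0, 2 * np.pi)
        )
    rr, cc = polygon(
        center[0] + radius * np.cos(theta),
        center[1] + radius * np.sin(theta),
        shape=(p.image_size, p.image_size),
    )
    mask = np.zeros((p.image_size, p.image_size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _render_slice(
    rng: np.random.Generator, p: PhantomParams, cls: dict, patient_offset: float
) -> TumorCase | tuple[np.ndarray, np.ndarray]:
    mask = _tumor_mask(rng, p)
    size = (p.image_size, p.image_size)
    image = p.background_mean + rng.normal(0, p.background_noise_sd, size)
    # context annulus: class-specific mean around the tumor
    annulus = ndimage.binary_dilation(
        mask, structure=disk_footprint(cls["ctx_width"])
    ) & ~mask
    image[annulus] = cls["ctx_mean"] + rng.normal(
        0, p.background_noise_sd, int(annulus.sum())
    )
    # tumor interior: smoothed noise rescaled to the class texture statistics
    noise = ndimage.gaussian_filter(rng.normal(0, 1, size), cls["tex_len"])
    noise /= max(noise.std(), 1e-12)
    image[mask] = cls["tex_mean"] + cls["tex_sd"] * noise[mask]
    image += patient_offset
    return image, mask


def generate_cohort(params: PhantomParams) -> Cohort:
    """Generate a labeled phantom cohort; a fixed seed fixes the cohort."""
    rng = np.random.default_rng(params.seed)
    class_params = _class_params(params)
    cases: list[TumorCase] = []
    lo, hi = params.slices_per_patient
    for i in range(params.n_patients):
        label = i % params.n_classes + 1  # round-robin keeps classes balanced
        cls = class_params[label - 1]
        pid = f"P{i:04d}"
        offset = rng.normal(0, params.patient_offset_sd)
        n_slices = int(rng.integers(lo, hi + 1))
        for _ in range(n_slices):
            image, mask = _render_slice(rng, params, cls, offset)
            cases.append(
                TumorCase(image=image, tumor_mask=mask, label=label, patient_id=pid)
            )
    return Cohort(cases=cases, class_set=frozenset(range(1, params.n_classes + 1)))


def perturb_mask(mask: np.ndarray, magnitude: int, seed: int) -> np.ndarray:
    """Morphologically jitter a mask: random shift plus dilation/erosion.

    Emulates an imprecise manual outline; the result always overlaps the
    original (falls back to the unshifted mask if the jitter would destroy
    all overlap).  ``magnitude=0`` returns an identical copy.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("cannot perturb an empty mask")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    shift = rng.integers(-magnitude, magnitude + 1, size=2)
    out = ndimage.shift(mask.astype(np.uint8), shift, order=0, cval=0).astype(bool)
    radius = int(rng.integers(0, magnitude + 1))
    if radius > 0:
        fp = disk_footprint(radius)
        if rng.random() < 0.5:
            out = ndimage.binary_dilation(out, structure=fp)
        else:
            eroded = ndimage.binary_erosion(out, structure=fp)
            if eroded.any():
                out = eroded
    if not (out & mask).any():  # guarantee Jaccard > 0
        return mask.copy()
    return out
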