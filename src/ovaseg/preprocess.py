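"""Ovary-enhancing intensity remap and slice-level training augmentation.

The remap brightens the narrow normalized-intensity band where ovarian tissue
sits on T2 fat-suppressed scans (by default [0.22, 0.30)) to 1, leaves other
dark tissue untouched, and inverts bright voxels (fluid, fat remnants) so that
nothing else in the image competes with the highlighted band:

    I'(x) = I0(x)        if I0(x) < o1
          = 1            if o1 <= I0(x) < o2
          = I0(x)        if o2 <= I0(x) < 0.5
          = 1 - I0(x)    if I0(x) >= 0.5

The augmentation protocol grows a training set by an integer factor using
random in-plane translations and rotations, with the identical rigid transform
applied to a slice and its mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DomainError
from .volume_io import Volume3D

__all__ = ["RemapParams", "AugmentParams", "remap_intensity", "augment_slices"]


@dataclass(frozen=True)
class RemapParams:
    """Band edges of the ovary intensity window, on the normalized [0,1] scale."""

    o1: float = 0.22
    o2: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 <= self.o1 < self.o2 <= 0.5):
            raise DomainError(f"require 0 <= o1 < o2 <= 0.5, got o1={self.o1}, o2={self.o2}")


@dataclass(frozen=True)
class AugmentParams:
    max_shift: float = 25.0  # pixels
    max_rot: float = 25.0  # degrees
    factor: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise DomainError("factor must be >= 1")
        if self.max_shift < 0 or self.max_rot < 0:
            raise DomainError("max_shift and max_rot must be >= 0")


def remap_intensity(v, p: RemapParams = RemapParams()):
    """Apply the piecewise ovary-enhancing map voxel-wise.

    Accepts a :class:`Volume3D` (returns one) or a bare ndarray / scalar in
    [0, 1] (returns the mapped array).  Exactly one branch fires per value;
    the output stays in [0, 1].
    """
    if isinstance(v, Volume3D):
        return replace(v, voxels=remap_intensity(v.voxels, p))
    x = np.asarray(v, dtype=np.float64)
    if x.size and (x.min() < 0.0 or x.max() > 1.0):
        raise DomainError("remap_intensity expects normalized intensities in [0, 1]")
    out = x.copy()
    out[(x >= p.o1) & (x < p.o2)] = 1.0
    inv = x >= 0.5
    out[inv] = 1.0 - x[inv]
    return out


def augment_slices(
    slices: np.ndarray,
    masks: np.ndarray,
    p: AugmentParams = AugmentParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Expand (slice, mask) pairs by ``p.factor`` with random rigid transforms.

    The output contains the untouched originals plus ``factor - 1`` augmented
    copies of each pair.  Per copy one rotation (uniform in [-max_rot,
    max_rot] degrees) and one translation (uniform in [-max_shift, max_shift]
    per axis, in pixels) are drawn and applied identically to slice and mask;
    images are interpolated bilinearly, masks nearest-neighbour, and pixels
    moved in from outside the frame are 0.  Fully reproducible from ``p.seed``.
    """
    slices = np.asarray(slices, dtype=np.float64)
    masks = np.asarray(masks)
    if slices.shape != masks.shape:
        raise AlignmentError(
            f"slices {slices.shape} and masks {masks.shape} must be aligned"
        )
    if slices.ndim != 3:
        raise AlignmentError("expected (n, H, W) stacks")

    rng = np.random.default_rng(p.seed)
    out_s = [slices]
    out_m = [(masks > 0.5).astype(np.float64)]
    n = slices.shape[0]
    for _ in range(p.factor - 1):
        aug_s = np.empty_like(slices)
        aug_m = np.empty_like(slices)
        for i in range(n):
            angle = rng.uniform(-p.max_rot, p.max_rot)
            shift = rng.uniform(-p.max_shift, p.max_shift, size=2)
            img, msk = slices[i], (masks[i] > 0.5).astype(np.float64)
            if angle != 0.0:
                img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
                msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant", cval=0.0)
            if shift[0] != 0.0 or shift[1] != 0.0:
                img = ndimage.shift(img, shift, order=1, mode="constant", cval=0.0)
                msk = ndimage.shift(msk, shift, order=0, mode="constant", cval=0.0)
            aug_s[i] = img
            aug_m[i] = (msk > 0.5).astype(np.float64)
        out_s.append(aug_s)
        out_m.append(aug_m)
    return np.concatenate(out_s, axis=0), np.concatenate(out_m, axis=0)
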