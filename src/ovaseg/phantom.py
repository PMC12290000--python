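"""Synthetic pelvic-MRI-like phantoms with ground truth and simulated raters.

The phantoms are not anatomically realistic: organs are ellipsoids, because an
ellipsoid has an analytic volume and an exactly known rasterized mask.  What
the generator does reproduce is the *intensity structure* a normalized
T2 fat-suppressed pelvic scan presents to the segmentation cascade:

* ovary-like ellipsoids whose pre-noise intensities lie inside the ovary
  band [0.22, 0.30) of the default intensity remap,
* a larger uterus-like structure at an intermediate intensity,
* bright fluid/fat-like blobs (> 0.5) that exercise the inversion branch of
  the remap and, placed adjacent to the ovary, create the classic
  false-positive scenario for postprocessing,
* additive Gaussian noise, and
* simulated raters whose contours disagree through smooth boundary jitter
  plus a systematic dilation/erosion bias.

Everything is reproducible from seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PlacementError
from .volume_io import LabelMap, MANIFEST_COLUMNS, Volume3D, write_nifti

__all__ = [
    "PhantomSpec",
    "RaterModel",
    "generate_phantom",
    "simulate_rater",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic pelvic volume.

    Radii are in mm; intensities on the normalized [0, 1] scale.  The default
    ovary band sits strictly inside the default remap window so that, with
    ``noise_sd = 0``, the remap maps every ground-truth ovary voxel to 1.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    n_ovaries: int = 2
    ovary_radii: tuple[float, float] = (9.0, 14.0)  # mm, per semi-axis
    ovary_intensity: tuple[float, float] = (0.22, 0.30)
    uterus_radii: tuple[float, float] = (24.0, 38.0)
    uterus_intensity: tuple[float, float] = (0.35, 0.45)
    n_bright_structures: int = 2
    bright_radii: tuple[float, float] = (8.0, 16.0)
    bright_intensity: tuple[float, float] = (0.6, 0.95)
    background_intensity: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0


@dataclass(frozen=True)
class RaterModel:
    """A simulated annotator: smooth boundary jitter plus a size bias.

    ``jitter_sd`` is the standard deviation (mm) of a band-limited random
    displacement field applied to the true contour; ``bias`` dilates (positive)
    or erodes (negative) the jittered mask by that many voxels.
    """

    rater_id: str
    jitter_sd: float = 0.0  # mm
    bias: int = 0  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, dict[str, LabelMap]]:
    """Generate one phantom volume and its ground-truth structure masks.

    Organs are placed by rejection sampling so their masks never overlap
    (bounded retries, then :class:`PlacementError`).  Pre-noise intensities
    are drawn per voxel, uniformly within each structure's band.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing
    fov = np.array([n * s for n, s in zip(shape, spacing)])

    vol = np.full(shape, spec.background_intensity, dtype=np.float64)
    occupied = np.zeros(shape, dtype=bool)
    masks: dict[str, np.ndarray] = {
        "uterus": np.zeros(shape, dtype=bool),
        "ovary": np.zeros(shape, dtype=bool),
    }

    def place(radii_range: tuple[float, float], near: np.ndarray | None = None,
              n_radii: int = 3) -> np.ndarray:
        nonlocal occupied
        for _ in range(200):
            radii = rng.uniform(*radii_range, size=n_radii)
            if near is None:
                center = rng.uniform(radii + 2.0, fov - radii - 2.0)
            else:
                offset = rng.uniform(-1.5, 1.5, size=3) * radii
                offset += np.sign(offset) * radii  # push off-center
                center = np.clip(near + offset, radii, fov - radii)
            m = _ellipsoid_mask(shape, spacing, center, radii)
            if not m.any():
                continue
            if not (m & occupied).any():
                occupied |= m
                return m
        raise PlacementError("could not place an organ without overlap after 200 tries")

    # uterus first (largest), roughly central
    for _ in range(200):
        radii = rng.uniform(*spec.uterus_radii, size=3)
        center = fov / 2.0 + rng.uniform(-0.1, 0.1, size=3) * fov
        center = np.clip(center, radii, fov - radii)
        m = _ellipsoid_mask(shape, spacing, center, radii)
        if m.any():
            masks["uterus"] = m
            occupied |= m
            break
    else:  # pragma: no cover - the default grid always fits a uterus
        raise PlacementError("could not place the uterus")

    ovary_center_mm = None
    for _ in range(spec.n_ovaries):
        m = place(spec.ovary_radii)
        masks["ovary"] |= m
        if ovary_center_mm is None:
            idx = np.array(ndimage.center_of_mass(m))
            ovary_center_mm = idx * np.array(spacing)

    bright = np.zeros(shape, dtype=bool)
    for i in range(spec.n_bright_structures):
        near = ovary_center_mm if (i == 0 and ovary_center_mm is not None) else None
        try:
            m = place(spec.bright_radii, near=near)
        except PlacementError:
            m = place(spec.bright_radii)  # fall back to anywhere free
        bright |= m

    for name, band in (
        ("uterus", spec.uterus_intensity),
        ("ovary", spec.ovary_intensity),
    ):
        m = masks[name]
        vol[m] = rng.uniform(band[0], np.nextafter(band[1], band[0]), size=int(m.sum()))
    vol[bright] = rng.uniform(*spec.bright_intensity, size=int(bright.sum()))

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = np.clip(vol, 0.0, 1.0)

    volume = Volume3D(voxels=vol, spacing=spacing)
    label_maps = {
        name: LabelMap(mask=m, spacing=spacing, structure=name, rater_id="truth")
        for name, m in masks.items()
    }
    return volume, label_maps


def simulate_rater(gt: LabelMap, model: RaterModel) -> LabelMap:
    """Perturb a ground-truth mask the way a human contour differs from truth.

    A smooth (band-limited) random displacement field with pointwise standard
    deviation ``jitter_sd`` mm warps the mask, then ``bias`` voxels of uniform
    dilation (+) or erosion (-) are applied.  ``jitter_sd = 0`` and
    ``bias = 0`` return the ground truth voxel-for-voxel.
    """
    mask = gt.mask.astype(np.float64)
    out = mask.copy()

    if model.jitter_sd > 0 and mask.any():
        rng = np.random.default_rng(model.seed)
        # the warp only matters near the object: work on a padded bounding box
        margin = np.ceil(4.0 * model.jitter_sd / np.array(gt.spacing)).astype(int) + 2
        nz = np.nonzero(mask)
        lo = [max(int(n.min()) - m, 0) for n, m in zip(nz, margin)]
        hi = [min(int(n.max()) + m + 1, s) for n, s, m in zip(nz, mask.shape, margin)]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = mask[box]
        shape = np.array(sub.shape)
        # low-resolution noise upsampled -> smooth displacement, per axis in mm
        coarse = np.maximum(shape // 8, 2)
        disp = []
        for axis in range(3):
            field_lo = rng.normal(0.0, 1.0, size=tuple(coarse))
            field_hi = ndimage.zoom(field_lo, shape / coarse, order=3)
            field_hi = field_hi[: shape[0], : shape[1], : shape[2]]
            sd = field_hi.std()
            if sd > 0:
                field_hi = field_hi / sd * model.jitter_sd / gt.spacing[axis]
            disp.append(field_hi)
        idx = np.meshgrid(*[np.arange(n) for n in sub.shape], indexing="ij")
        coords = [i + d for i, d in zip(idx, disp)]
        warped = ndimage.map_coordinates(sub, coords, order=1, mode="nearest")
        out[box] = warped
        out = (out > 0.5).astype(np.float64)

    if model.bias > 0:
        out = ndimage.binary_dilation(out > 0.5, iterations=model.bias)
    elif model.bias < 0:
        out = ndimage.binary_erosion(out > 0.5, iterations=-model.bias)

    return LabelMap(
        mask=out,
        spacing=gt.spacing,
        structure=gt.structure,
        rater_id=model.rater_id,
        subject_id=gt.subject_id,
    )


def generate_cohort(
    out_dir: str | Path,
    n_subjects: int,
    spec: PhantomSpec = PhantomSpec(),
    rater_models: list[RaterModel] = (),
    seed: int = 0,
    structures: tuple[str, ...] = ("uterus", "ovary"),
    write_truth: bool = True,
) -> Path:
    """Write a cohort of phantom subjects in the standard NIfTI + manifest layout.

    Per subject: one volume ``<root>/<subject>/t2fs.nii.gz`` and one mask
    ``<root>/<subject>/<structure>_<rater>.nii.gz`` per structure and rater
    (plus the ground truth under rater id "truth" when ``write_truth``).
    Subject seeds derive deterministically from ``seed`` and the subject
    index.  Returns the manifest CSV path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_subjects):
        subject = f"subj{i:03d}"
        sub_seed = (seed * 100003 + i * 1009) % (2**31 - 1)
        sspec = PhantomSpec(**{**spec.__dict__, "seed": sub_seed})
        volume, gt_masks = generate_phantom(sspec)
        volume.subject_id = subject
        subj_dir = out_dir / subject
        vol_path = subj_dir / "t2fs.nii.gz"
        write_nifti(volume, vol_path)
        rows.append(
            {"subject": subject, "kind": "volume", "structure": "", "rater": "",
             "path": str(vol_path.relative_to(out_dir))}
        )
        for structure in structures:
            gt = gt_masks[structure]
            gt.subject_id = subject
            if write_truth:
                p = subj_dir / f"{structure}_truth.nii.gz"
                write_nifti(gt, p)
                rows.append(
                    {"subject": subject, "kind": "mask", "structure": structure,
                     "rater": "truth", "path": str(p.relative_to(out_dir))}
                )
            for j, model in enumerate(rater_models):
                rm_seed = (
                    sub_seed + 7919 * (j + 1) + zlib.crc32(structure.encode()) % 1000
                ) % (2**31 - 1)
                rm = RaterModel(
                    rater_id=model.rater_id,
                    jitter_sd=model.jitter_sd,
                    bias=model.bias,
                    seed=rm_seed,
                )
                lm = simulate_rater(gt, rm)
                p = subj_dir / f"{structure}_{model.rater_id}.nii.gz"
                write_nifti(lm, p)
                rows.append(
                    {"subject": subject, "kind": "mask", "structure": structure,
                     "rater": model.rater_id, "path": str(p.relative_to(out_dir))}
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
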