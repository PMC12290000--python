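"""NIfTI I/O, intensity normalization, slice resampling and volume bookkeeping.

The package treats a 3D scan as a plain voxel grid plus per-axis spacing in
millimetres.  By convention the third grid axis is the slice (axial) axis;
physical position along an axis is ``index * spacing`` (the NIfTI affine is
preserved on round trip but not used in computation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    AlignmentError,
    DegenerateInputError,
    MetadataError,
    ShapeError,
)

STRUCTURES = ("uterus", "ovary", "endometrioma", "cyst")


@dataclass
class Volume3D:
    """A 3D scalar image with per-axis spacing in mm.

    ``voxels`` holds arbitrary intensity units before normalization and values
    in [0, 1] afterwards.  ``axis_order`` names the slice axis; only the
    default ("xyz", slices along axis 2) is used by the pipeline.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "xyz"
    subject_id: str = ""
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ShapeError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


@dataclass
class LabelMap:
    """A binary mask aligned to a parent :class:`Volume3D` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    structure: str = "ovary"
    rater_id: str = ""
    subject_id: str = ""
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ShapeError(f"expected a 3D mask, got ndim={self.mask.ndim}")
        self.mask = (self.mask > 0.5).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass
class SliceStack:
    """Ordered 2D slices taken along the slice axis of a volume."""

    slices: np.ndarray  # (n_slices, H, W)
    indices: np.ndarray  # original slice index along the slice axis
    spacing: tuple[float, float]  # in-plane spacing of the (possibly resampled) grid

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ShapeError("SliceStack expects an (n, H, W) array")
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) != self.slices.shape[0]:
            raise AlignmentError("one index per slice required")

    def __len__(self) -> int:
        return self.slices.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.slices)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _spacing_from_img(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_nifti(
    path: str | os.PathLike,
    *,
    as_mask: bool = False,
    structure: str = "ovary",
    rater_id: str = "",
    subject_id: str = "",
) -> Volume3D | LabelMap:
    """Load a NIfTI-1 volume (or, with ``as_mask=True``, a binary label map).

    Masks are binarized by thresholding the stored values at 0.5, so label
    files stored as {0, 255} or probabilities load to {0, 1}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path.name}: expected a 3D image, got ndim={data.ndim}")
    spacing = _spacing_from_img(img)
    if as_mask:
        return LabelMap(
            mask=data,
            spacing=spacing,
            structure=structure,
            rater_id=rater_id,
            subject_id=subject_id,
            affine=np.asarray(img.affine),
        )
    return Volume3D(
        voxels=data.astype(np.float64),
        spacing=spacing,
        subject_id=subject_id,
        affine=np.asarray(img.affine),
    )


def write_nifti(obj: Volume3D | LabelMap, path: str | os.PathLike) -> Path:
    """Write a volume or mask to ``path`` (.nii or .nii.gz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, LabelMap):
        data = obj.mask.astype(np.uint8)
    else:
        data = obj.voxels.astype(np.float32)
    affine = obj.affine if obj.affine is not None else np.diag([*obj.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_volume(v: Volume3D, p_low: float = 1.0, p_high: float = 99.0) -> Volume3D:
    """Clip to the [p_low, p_high] percentiles and map affinely onto [0, 1].

    Percentiles are computed over all voxels of the volume (background
    included), as order statistics (lower / higher) rather than interpolated
    values: the clip then leaves at least one exact tie at each extreme, which
    makes the operation exactly idempotent.  A constant volume has no usable
    contrast and raises :class:`DegenerateInputError`.
    """
    vox = v.voxels
    q_low = np.percentile(vox, p_low, method="lower")
    q_high = np.percentile(vox, p_high, method="higher")
    if q_high <= q_low:
        raise DegenerateInputError(
            "volume has no intensity spread between the requested percentiles"
        )
    out = np.clip(vox, q_low, q_high)
    out = (out - q_low) / (q_high - q_low)
    return replace(v, voxels=out)


# ---------------------------------------------------------------------------
# Slice resampling
# ---------------------------------------------------------------------------

def resample_slice_stack(
    v: Volume3D | LabelMap,
    out_size: int = 512,
    out_spacing: float = 5.0,
    is_mask: bool | None = None,
) -> SliceStack:
    """Resample every axial slice to ``out_size``^2 pixels at ``out_spacing`` mm.

    Output pixel (i, j) samples the input at physical position
    (i * out_spacing, j * out_spacing); images use linear interpolation, masks
    nearest-neighbour (so labels stay binary).  Positions outside the input
    grid are filled with 0.  The slice count is unchanged.
    """
    if is_mask is None:
        is_mask = isinstance(v, LabelMap)
    data = v.mask if isinstance(v, LabelMap) else v.voxels
    sx, sy, _ = v.spacing
    if sx <= 0 or sy <= 0:
        raise MetadataError("in-plane spacing must be known and positive")

    coords = np.arange(out_size, dtype=np.float64) * out_spacing
    ix = coords / sx
    iy = coords / sy
    gx, gy = np.meshgrid(ix, iy, indexing="ij")

    order = 0 if is_mask else 1
    n = data.shape[2]
    out = np.empty((n, out_size, out_size), dtype=np.float64)
    for k in range(n):
        out[k] = ndimage.map_coordinates(
            data[:, :, k].astype(np.float64),
            [gx, gy],
            order=order,
            mode="constant",
            cval=0.0,
        )
    if is_mask:
        out = (out > 0.5).astype(np.float64)
    return SliceStack(slices=out, indices=np.arange(n), spacing=(out_spacing, out_spacing))


def restack_to_volume(
    stack: SliceStack,
    like: Volume3D,
    is_mask: bool = True,
) -> np.ndarray:
    """Inverse of :func:`resample_slice_stack`: map slices back to the native grid.

    Nearest-neighbour sampling for masks keeps the result binary.
    """
    sx, sy, _ = like.spacing
    nx, ny, nz = like.shape
    if len(stack) != nz:
        raise AlignmentError("slice count must equal the target volume's slice extent")
    out_spacing = stack.spacing[0]
    ix = np.arange(nx, dtype=np.float64) * sx / out_spacing
    iy = np.arange(ny, dtype=np.float64) * sy / out_spacing
    gx, gy = np.meshgrid(ix, iy, indexing="ij")
    order = 0 if is_mask else 1
    out = np.empty((nx, ny, nz), dtype=np.float64)
    for k in range(nz):
        out[:, :, k] = ndimage.map_coordinates(
            stack.slices[k], [gx, gy], order=order, mode="constant", cval=0.0
        )
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def volume_cc(m: LabelMap, spacing: tuple[float, float, float] | None = None) -> float:
    """Mask volume in cubic centimetres: (#positive voxels) * voxel volume / 1000."""
    sp = m.spacing if spacing is None else spacing
    voxel_mm3 = float(sp[0]) * float(sp[1]) * float(sp[2])
    return float(m.mask.sum()) * voxel_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject", "kind", "structure", "rater", "path"]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV (columns: subject, kind, structure, rater, path).

    ``kind`` is "volume" or "mask"; volume rows leave structure/rater empty.
    Paths are interpreted relative to the manifest's directory when not
    absolute.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"manifest is missing columns: {sorted(missing)}")
    root = path.parent

    def _abs(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else root / q)

    df = df.copy()
    df["path"] = df["path"].map(_abs)
    return df


def load_cohort(
    manifest: str | os.PathLike | pd.DataFrame,
) -> dict[str, dict]:
    """Load a full cohort described by a manifest.

    Returns ``{subject: {"volume": Volume3D, "masks": {structure: {rater: LabelMap}}}}``.
    """
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    cohort: dict[str, dict] = {}
    for subject, grp in df.groupby("subject", sort=True):
        entry: dict = {"volume": None, "masks": {}}
        for row in grp.itertuples(index=False):
            if row.kind == "volume":
                entry["volume"] = read_nifti(row.path, subject_id=subject)
            else:
                lm = read_nifti(
                    row.path,
                    as_mask=True,
                    structure=row.structure,
                    rater_id=row.rater,
                    subject_id=subject,
                )
                entry["masks"].setdefault(row.structure, {})[row.rater] = lm
        cohort[subject] = entry
    return cohort
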