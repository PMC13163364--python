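"""Volumes, masks and the common kidney-centered lattice.

All arrays in this package are indexed ``(z, y, x)`` with ``z`` the slice
axis (0-based). NIfTI stores axes fastest-first as ``(x, y, z)``; readers
and writers transpose so that in-memory axis 0 is always the slice axis and
``spacing`` is reported in the same ``(z, y, x)`` order, in millimetres.

Cohort-level operations (shape prior averaging, condition-volume stacking)
require voxelwise correspondence across subjects, which is established by
cropping every subject to one fixed kidney-centered ROI per cohort
(:func:`extract_roi`). Out-of-bounds regions are zero-padded for both image
and mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "GridVolume",
    "BinaryMask",
    "RoiSpec",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_centroid",
    "extract_roi",
    "normalize_intensity",
]


@dataclass
class GridVolume:
    """A 3D scalar field on a regular lattice.

    Parameters
    ----------
    data:
        3D float array indexed ``(z, y, x)``.
    spacing:
        Voxel spacing in mm per axis, ``(z, y, x)`` order, strictly positive.
    origin_tag:
        Free-form subject/provenance identifier.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A {0,1} field on the same lattice as its paired :class:`GridVolume`."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be exactly {{0,1}}, found {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass
class RoiSpec:
    """A fixed-size kidney-centered crop specification.

    ``size`` is held fixed across a cohort so that all condition volumes are
    identically shaped. In ``train`` mode the center defaults to the paired
    mask's centroid; in ``inference`` mode the caller must supply a center
    (the held-out subject has no reference mask).
    """

    size: Tuple[int, int, int]
    center: Optional[Tuple[int, int, int]] = None
    mode: str = "train"

    def __post_init__(self) -> None:
        if self.mode not in ("train", "inference"):
            raise ValueError(f"mode must be 'train' or 'inference', got {self.mode!r}")
        if len(self.size) != 3 or any(int(s) < 1 for s in self.size):
            raise ValueError(f"size must be three positive ints, got {self.size}")
        self.size = tuple(int(s) for s in self.size)
        if self.center is not None:
            self.center = tuple(int(c) for c in self.center)


def _load_nifti(path) -> tuple[np.ndarray, Tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected 3D volume, got {arr.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI axes are (x, y, z); flip to the package's (z, y, x) convention.
    return np.transpose(arr, (2, 1, 0)), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def read_volume(path) -> GridVolume:
    """Read a 3D NIfTI image as a :class:`GridVolume`.

    Intensities are cast to float32; spacing is taken from the header.
    Rejects non-3D images and non-finite voxels.
    """
    data, spacing = _load_nifti(path)
    data = data.astype(np.float32)
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite voxels in {path}")
    return GridVolume(data=data, spacing=spacing, origin_tag=str(Path(path).name))


def write_volume(vol: GridVolume, path) -> None:
    """Write a :class:`GridVolume` to NIfTI, inverting the axis convention."""
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    arr = np.transpose(np.asarray(vol.data), (2, 1, 0))
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    """Read a binary mask from NIfTI; values must be exactly {0,1}."""
    data, spacing = _load_nifti(path)
    return BinaryMask(data=data, spacing=spacing)


def write_mask(mask: BinaryMask, path) -> None:
    affine = np.diag([mask.spacing[2], mask.spacing[1], mask.spacing[0], 1.0])
    arr = np.transpose(mask.data.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, str(path))


def mask_centroid(mask: BinaryMask) -> Tuple[int, int, int]:
    """Arithmetic mean of foreground voxel indices, rounded to the nearest voxel."""
    if mask.is_empty():
        raise ValueError("centroid undefined for an empty mask")
    coords = np.argwhere(mask.data)
    center = np.rint(coords.mean(axis=0)).astype(int)
    return (int(center[0]), int(center[1]), int(center[2]))


def _crop_axis(extent: int, center: int, size: int) -> tuple[slice, slice]:
    """Source and destination slices for a centered crop with zero padding."""
    start = center - size // 2
    src_lo = max(start, 0)
    src_hi = min(start + size, extent)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    return slice(src_lo, src_hi), slice(dst_lo, dst_hi)


def extract_roi(
    vol: GridVolume,
    mask: Optional[BinaryMask],
    spec: RoiSpec,
) -> tuple[GridVolume, Optional[BinaryMask]]:
    """Crop a fixed-size kidney-centered ROI, zero-padding out-of-bounds voxels.

    In ``train`` mode the crop center defaults to ``mask_centroid(mask)``; a
    missing or empty mask is an error there. In ``inference`` mode
    ``spec.center`` must be supplied (typically the cohort-mean training
    centroid). The mask, when present, is cropped identically.
    """
    if spec.mode == "train":
        if mask is None or mask.is_empty():
            raise ValueError("train-mode ROI requires a non-empty mask (centroid undefined)")
        center = spec.center if spec.center is not None else mask_centroid(mask)
    else:
        if spec.center is None:
            raise ValueError("inference-mode ROI requires an explicit center")
        center = spec.center

    slices = [_crop_axis(vol.shape[i], center[i], spec.size[i]) for i in range(3)]
    out = np.zeros(spec.size, dtype=vol.data.dtype)
    src = tuple(s for s, _ in slices)
    dst = tuple(d for _, d in slices)
    out[dst] = vol.data[src]
    vol_roi = GridVolume(data=out, spacing=vol.spacing, origin_tag=vol.origin_tag)

    mask_roi = None
    if mask is not None:
        mout = np.zeros(spec.size, dtype=np.uint8)
        mout[dst] = mask.data[src]
        mask_roi = BinaryMask(data=mout, spacing=mask.spacing)
    return vol_roi, mask_roi


def normalize_intensity(vol: GridVolume, levels: int = 256) -> GridVolume:
    """Min-max rescale intensities onto the integer levels ``{0..levels-1}``.

    A constant volume maps to all zeros by convention. The map is monotone:
    ``g(a) <= g(b)`` implies ``norm(a) <= norm(b)``.
    """
    if levels < 1:
        raise ValueError("levels must be positive")
    data = np.asarray(vol.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        out = np.zeros(vol.shape, dtype=np.int32)
    else:
        out = np.rint((data - lo) / (hi - lo) * (levels - 1)).astype(np.int32)
    return GridVolume(data=out, spacing=vol.spacing, origin_tag=vol.origin_tag)
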