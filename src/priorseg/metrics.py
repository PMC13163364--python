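"""Segmentation metrics: Dice, IoU, HD95 and ASSD in physical units.

Overlap metrics (Dice, IoU) are voxel-count ratios; both-empty pairs score
1.0 by convention. Boundary metrics operate on surface voxels — foreground
voxels with at least one face-adjacent background neighbor, volume faces
counting as background — with distances measured in millimetres under
anisotropic voxel spacing. HD95 and ASSD are taken over the pooled
symmetric distance list (every boundary voxel of each mask to the nearest
boundary voxel of the other); the 95th percentile uses linear interpolation
between order statistics so results are bit-stable. Masks are never
resampled for metric computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import BinaryMask

__all__ = [
    "SegScores",
    "dice",
    "iou",
    "boundary_voxels",
    "surface_distances",
    "hd95",
    "assd",
    "score_pair",
]

_FACE3D = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegScores:
    """Per-subject scores; dice/iou are fractions, hd95/assd in mm."""

    dice: float
    iou: float
    hd95: float
    assd: float


def _check_lattice(pred: BinaryMask, ref: BinaryMask) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"lattice mismatch: {pred.shape} vs {ref.shape}")


def dice(pred: BinaryMask, ref: BinaryMask) -> float:
    """Dice coefficient 2|P∩R| / (|P| + |R|); both empty ⇒ 1.0."""
    _check_lattice(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / denom


def iou(pred: BinaryMask, ref: BinaryMask) -> float:
    """Jaccard index |P∩R| / |P∪R|; both empty ⇒ 1.0."""
    _check_lattice(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)
    union = int((p | r).sum())
    if union == 0:
        return 1.0
    return int((p & r).sum()) / union


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Indices of foreground voxels with a face-adjacent background neighbor.

    The volume faces count as background, so foreground touching the edge of
    the array is part of the surface.
    """
    fg = mask.data.astype(bool)
    eroded = ndimage.binary_erosion(fg, structure=_FACE3D, border_value=0)
    return np.argwhere(fg & ~eroded)


def surface_distances(
    pred: BinaryMask, ref: BinaryMask, spacing: Tuple[float, float, float]
) -> np.ndarray:
    """Sorted pooled symmetric surface distances in mm.

    For each boundary voxel of the prediction, the distance to the nearest
    boundary voxel of the reference, and vice versa, under anisotropic
    physical spacing.
    """
    _check_lattice(pred, ref)
    if pred.is_empty() or ref.is_empty():
        raise ValueError("undefined surface distance: empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    bp = boundary_voxels(pred) * sp
    br = boundary_voxels(ref) * sp
    d_pr, _ = cKDTree(br).query(bp, k=1)
    d_rp, _ = cKDTree(bp).query(br, k=1)
    return np.sort(np.concatenate([d_pr, d_rp]))


def hd95(pred: BinaryMask, ref: BinaryMask, spacing: Tuple[float, float, float]) -> float:
    """95th percentile (linear interpolation) of the symmetric surface distances."""
    return float(np.percentile(surface_distances(pred, ref, spacing), 95))


def assd(pred: BinaryMask, ref: BinaryMask, spacing: Tuple[float, float, float]) -> float:
    """Mean of the pooled symmetric surface distances."""
    return float(np.mean(surface_distances(pred, ref, spacing)))


def score_pair(
    pred: BinaryMask, ref: BinaryMask, spacing: Tuple[float, float, float]
) -> SegScores:
    """All four metrics for one prediction/reference pair.

    Surface metrics are NaN sentinels when either mask is empty; the
    cross-validation pipeline flags such cases instead of crashing.
    """
    d = dice(pred, ref)
    j = iou(pred, ref)
    if pred.is_empty() or ref.is_empty():
        return SegScores(dice=d, iou=j, hd95=float("nan"), assd=float("nan"))
    dists = surface_distances(pred, ref, spacing)
    return SegScores(
        dice=d,
        iou=j,
        hd95=float(np.percentile(dists, 95)),
        assd=float(np.mean(dists)),
    )
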