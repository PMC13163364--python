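"""Cohort-averaged anatomical shape prior.

The shape prior is the voxelwise mean of the training-fold binary masks on
the common kidney-centered ROI grid: ``S(x) = (1/N) Σ_n M_n(x)``. Every
value is an exact rational ``k/N``; voxels consistently labeled kidney
approach 1, background approaches 0, and anatomically variable boundary
zones take intermediate values. It is recomputed per cross-validation fold
(and per modality) from reference-set masks only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import BinaryMask

__all__ = ["ShapePrior", "build_shape_prior", "binarize_prior"]


@dataclass
class ShapePrior:
    """[0,1] field of cohort mask frequency on the common ROI lattice."""

    s: np.ndarray
    n_subjects: int


def build_shape_prior(masks: Sequence[BinaryMask]) -> ShapePrior:
    """Voxelwise average of training masks on a common lattice."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    acc = np.zeros(shape, dtype=np.float64)
    for m in masks:
        acc += m.data
    return ShapePrior(s=acc / len(masks), n_subjects=len(masks))


def binarize_prior(prior: ShapePrior, tau: float = 0.5) -> BinaryMask:
    """Threshold the prior at ``tau``; ties (s == tau) resolve to foreground."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0,1], got {tau}")
    return BinaryMask(data=(prior.s >= tau).astype(np.uint8))
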