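"""Voxelwise probabilistic appearance prior from contour-band histograms.

The appearance model stratifies intensity statistics spatially: each axial
slice is partitioned into concentric iso-contour bands of fixed thickness
around the kidney boundary (distance-to-boundary shells, on both sides of
the contour; boundary voxels themselves are band 1). Within each band,
foreground and background histograms of a neighborhood intensity response
are accumulated over all training subjects. At inference, each banded voxel
is scored by the kidney likelihood

    P = H_K(I) / (H_K(I) + H_B(I))

for its response level I and band; empty histogram bins fall back to
symmetric pooling over neighboring gray levels I±δ for δ = 1..3, and to the
neutral value 0.5 when no support exists within that tolerance.

The neighborhood response Φ sums quantized intensities over in-plane
neighbors (Chebyshev radius ``radius``) on slices z-1, z, z+1 that share the
center voxel's band label. For histogramming, Φ is divided by the number of
contributing voxels and rounded, keeping the response on the quantized
intensity scale regardless of neighborhood occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, GridVolume

__all__ = [
    "ContourBandField",
    "NeighborhoodResponse",
    "AppearanceModel",
    "AppearanceMap",
    "band_partition",
    "neighborhood_response",
    "accumulate_histograms",
    "likelihood",
    "appearance_map",
]

UNASSIGNED = 0


@dataclass
class ContourBandField:
    """Per-voxel contour-band labels.

    ``band_label`` holds integers in ``{1..n_bands}`` on slices where the
    reference mask is non-empty and ``0`` (unassigned) elsewhere. Band
    ``c = max(1, ceil(d / thickness))`` capped at ``n_bands``, where ``d`` is
    the in-plane Euclidean distance to the reference boundary.
    """

    band_label: np.ndarray
    n_bands: int
    thickness: int


@dataclass
class NeighborhoodResponse:
    """Summed same-band neighborhood intensities Φ and occupancy counts."""

    phi: np.ndarray
    count: np.ndarray
    radius: int

    def levels(self) -> np.ndarray:
        """Φ normalized by occupancy and rounded back to the intensity scale."""
        out = np.zeros(self.phi.shape, dtype=np.int64)
        nz = self.count > 0
        out[nz] = np.rint(self.phi[nz] / self.count[nz]).astype(np.int64)
        return out


@dataclass
class AppearanceModel:
    """Per-band foreground/background histograms of neighborhood responses."""

    hist_fg: np.ndarray  # (n_bands, levels) integer counts
    hist_bg: np.ndarray
    n_bands: int
    thickness: int
    radius: int
    levels: int = 256
    delta_max: int = 3
    neutral: float = 0.5

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            hist_fg=self.hist_fg,
            hist_bg=self.hist_bg,
            meta=np.array(
                [self.n_bands, self.thickness, self.radius, self.levels, self.delta_max],
                dtype=np.int64,
            ),
            neutral=np.array([self.neutral]),
        )

    @classmethod
    def load(cls, path) -> "AppearanceModel":
        with np.load(path) as z:
            n_bands, thickness, radius, levels, delta_max = (int(v) for v in z["meta"])
            return cls(
                hist_fg=z["hist_fg"],
                hist_bg=z["hist_bg"],
                n_bands=n_bands,
                thickness=thickness,
                radius=radius,
                levels=levels,
                delta_max=delta_max,
                neutral=float(z["neutral"][0]),
            )


@dataclass
class AppearanceMap:
    """Voxelwise kidney likelihood in [0,1]; unassigned voxels carry 0.5."""

    papp: np.ndarray


def band_partition(reference_mask: BinaryMask, n_bands: int, thickness: int) -> ContourBandField:
    """Partition each slice into concentric iso-contour bands around the boundary.

    Per slice the unsigned Euclidean distance ``d`` to the boundary contour
    ``∂M_z`` is computed (boundary = foreground pixels with a 4-adjacent
    background pixel, slice edges counting as background). Voxels on the
    contour (d = 0) belong to band 1; otherwise band ``ceil(d / thickness)``,
    capped at ``n_bands``; bands extend on both sides of the contour. Slices
    with an empty reference are fully unassigned.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    mask = reference_mask.data.astype(bool)
    if not mask.any():
        raise ValueError("reference mask empty on every slice")
    labels = np.zeros(mask.shape, dtype=np.int16)
    for z in range(mask.shape[0]):
        sl = mask[z]
        if not sl.any():
            continue
        eroded = ndimage.binary_erosion(sl, structure=_CROSS2D, border_value=0)
        boundary = sl & ~eroded
        # distance from every pixel to the nearest boundary pixel
        d = ndimage.distance_transform_edt(~boundary)
        band = np.ceil(d / float(thickness)).astype(np.int16)
        band[band < 1] = 1
        np.minimum(band, n_bands, out=band)
        labels[z] = band
    return ContourBandField(band_label=labels, n_bands=n_bands, thickness=thickness)


_CROSS2D = ndimage.generate_binary_structure(2, 1)


def neighborhood_response(
    vol: GridVolume, bands: ContourBandField, radius: int = 1
) -> NeighborhoodResponse:
    """Sum quantized intensities over same-band neighbors on slices z-1..z+1.

    The neighborhood of a banded voxel contains all voxels within in-plane
    Chebyshev distance ``radius`` on the three slices z-1, z, z+1 whose band
    label equals the center voxel's; out-of-volume slices contribute
    nothing. Unassigned voxels get Φ = 0, count = 0.
    """
    if vol.data.shape != bands.band_label.shape:
        raise ValueError("volume and band field must share a lattice")
    intens = np.asarray(vol.data, dtype=np.int64)
    label = bands.band_label
    assigned = label != UNASSIGNED
    phi = np.zeros(intens.shape, dtype=np.int64)
    count = np.zeros(intens.shape, dtype=np.int64)
    D, H, W = intens.shape
    for dz in (-1, 0, 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                src_z = slice(max(dz, 0), D + min(dz, 0))
                dst_z = slice(max(-dz, 0), D + min(-dz, 0))
                src_y = slice(max(dy, 0), H + min(dy, 0))
                dst_y = slice(max(-dy, 0), H + min(-dy, 0))
                src_x = slice(max(dx, 0), W + min(dx, 0))
                dst_x = slice(max(-dx, 0), W + min(-dx, 0))
                same = (
                    assigned[dst_z, dst_y, dst_x]
                    & (label[dst_z, dst_y, dst_x] == label[src_z, src_y, src_x])
                )
                phi[dst_z, dst_y, dst_x] += np.where(same, intens[src_z, src_y, src_x], 0)
                count[dst_z, dst_y, dst_x] += same
    return NeighborhoodResponse(phi=phi, count=count, radius=radius)


def accumulate_histograms(
    training_pairs: Sequence[Tuple[GridVolume, BinaryMask]],
    n_bands: int = 8,
    thickness: int = 1,
    radius: int = 1,
    levels: int = 256,
) -> AppearanceModel:
    """Accumulate per-band fg/bg response histograms over training subjects.

    Volumes must already be quantized to ``{0..levels-1}``
    (:func:`priorseg.grid.normalize_intensity`). Per banded voxel, the
    normalized response level increments the foreground histogram of its
    band when the ground-truth mask is 1, else the background histogram;
    counts sum over subjects, so duplicating the training set doubles every
    count.
    """
    if len(training_pairs) == 0:
        raise ValueError("need at least one training pair")
    hist_fg = np.zeros((n_bands, levels), dtype=np.int64)
    hist_bg = np.zeros((n_bands, levels), dtype=np.int64)
    for vol, mask in training_pairs:
        if vol.data.shape != mask.data.shape:
            raise ValueError("volume/mask shape mismatch")
        if vol.data.min() < 0 or vol.data.max() > levels - 1:
            raise ValueError("volume must be quantized to the model's intensity levels")
        bands = band_partition(mask, n_bands=n_bands, thickness=thickness)
        resp = neighborhood_response(vol, bands, radius=radius)
        lev = resp.levels()
        sel = bands.band_label != UNASSIGNED
        b = bands.band_label[sel].astype(np.int64) - 1
        lv = np.clip(lev[sel], 0, levels - 1)
        fg = mask.data[sel].astype(bool)
        np.add.at(hist_fg, (b[fg], lv[fg]), 1)
        np.add.at(hist_bg, (b[~fg], lv[~fg]), 1)
    return AppearanceModel(
        hist_fg=hist_fg,
        hist_bg=hist_bg,
        n_bands=n_bands,
        thickness=thickness,
        radius=radius,
        levels=levels,
    )


def likelihood(model: AppearanceModel, intensity_level: int, band: int) -> float:
    """Kidney likelihood for one response level in one band.

    Returns ``H_K / (H_K + H_B)`` when the bin has support. Empty bins pool
    counts symmetrically over ``{I-δ, I+δ}`` for δ = 1..delta_max, returning
    the ratio at the first δ with support; with no support anywhere within
    tolerance the neutral 0.5 is returned.
    """
    if not (1 <= band <= model.n_bands):
        raise ValueError(f"band {band} out of range 1..{model.n_bands}")
    if not (0 <= intensity_level < model.levels):
        raise ValueError(f"intensity level {intensity_level} out of range 0..{model.levels - 1}")
    fg = model.hist_fg[band - 1]
    bg = model.hist_bg[band - 1]
    k, b = int(fg[intensity_level]), int(bg[intensity_level])
    if k + b > 0:
        return k / (k + b)
    for delta in range(1, model.delta_max + 1):
        k = b = 0
        for j in (intensity_level - delta, intensity_level + delta):
            if 0 <= j < model.levels:
                k += int(fg[j])
                b += int(bg[j])
        if k + b > 0:
            return k / (k + b)
    return model.neutral


def _likelihood_table(model: AppearanceModel) -> np.ndarray:
    """Vectorized per-(band, level) likelihood lookup table.

    Exactly reproduces :func:`likelihood` over the full level range,
    including the δ-expansion and the neutral fallback.
    """
    fg = model.hist_fg.astype(np.float64)
    bg = model.hist_bg.astype(np.float64)
    total = fg + bg
    table = np.full((model.n_bands, model.levels), model.neutral, dtype=np.float64)
    done = total > 0
    with np.errstate(invalid="ignore"):
        table[done] = (fg / total)[done]
    for delta in range(1, model.delta_max + 1):
        lo = np.arange(model.levels) - delta
        hi = np.arange(model.levels) + delta
        k = np.zeros_like(fg)
        b = np.zeros_like(bg)
        ok_lo, ok_hi = lo >= 0, hi < model.levels
        k[:, ok_lo] += fg[:, lo[ok_lo]]
        b[:, ok_lo] += bg[:, lo[ok_lo]]
        k[:, ok_hi] += fg[:, hi[ok_hi]]
        b[:, ok_hi] += bg[:, hi[ok_hi]]
        pooled = k + b
        hit = ~done & (pooled > 0)
        with np.errstate(invalid="ignore"):
            table[hit] = (k / np.where(pooled > 0, pooled, 1))[hit]
        done |= hit
    return table


def appearance_map(
    model: AppearanceModel, vol: GridVolume, bands: ContourBandField
) -> AppearanceMap:
    """Evaluate the voxelwise kidney-likelihood map for a quantized volume.

    Each banded voxel is scored by :func:`likelihood` at its neighborhood
    response level; unassigned voxels carry the neutral 0.5. At inference
    the band field comes from a mask-free reference (the binarized cohort
    shape prior), since the held-out subject has no ground-truth contour.
    """
    if vol.data.shape != bands.band_label.shape:
        raise ValueError("volume and band field must share a lattice")
    resp = neighborhood_response(vol, bands, radius=model.radius)
    lev = np.clip(resp.levels(), 0, model.levels - 1)
    table = _likelihood_table(model)
    papp = np.full(vol.data.shape, model.neutral, dtype=np.float64)
    sel = bands.band_label != UNASSIGNED
    papp[sel] = table[bands.band_label[sel].astype(np.int64) - 1, lev[sel]]
    return AppearanceMap(papp=papp)
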