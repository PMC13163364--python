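"""Synthetic kidney-transplant MRI phantoms.

Generates cohorts of (volume, mask) pairs with the statistical structure the
segmentation framework targets, so every other module is testable without
patient data:

* a single connected kidney-like object (rotated, jittered, optionally
  dented ellipsoid) whose pose varies per subject, emulating the
  graft-placement variability of transplant cohorts;
* foreground/background mean intensities with configurable overlap against
  additive Gaussian noise — the ``t2_like`` preset is the low-contrast
  regime, ``bold_like`` is intermediate with a crude through-slice signal
  decay (an echo-decay surrogate), and ``dw_like`` is high contrast, so the
  presets order contrast-to-noise as dw > bold > t2;
* a smooth multiplicative intensity-inhomogeneity (bias) field built from
  2-3 low-frequency cosine modes, a standard MRI surrogate.

This is deliberately not an MR physics simulation (no k-space, no sequence
modeling); it reproduces only the statistical challenges — noise, low
contrast, inhomogeneity, pose variability — that the priors and the
adversarial network are designed to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .grid import BinaryMask, GridVolume

__all__ = ["PhantomConfig", "make_subject", "make_cohort", "MODALITY_PRESETS"]

AxisRange = Tuple[float, float]

#: intensity presets per emulated modality: (fg_mean, bg_mean, noise_sd).
#: Contrast-to-noise |fg - bg| / noise_sd orders dw (10.0) > bold (2.75)
#: > t2 (1.6), mirroring how kidney-to-background contrast ranks across
#: DW, BOLD and T2-weighted acquisitions.
MODALITY_PRESETS: Dict[str, Tuple[float, float, float]] = {
    "t2_like": (140.0, 100.0, 25.0),
    "bold_like": (150.0, 95.0, 20.0),
    "dw_like": (200.0, 50.0, 15.0),
}


@dataclass
class PhantomConfig:
    """Cohort-level generator settings.

    Geometry is in voxels; intensities in arbitrary units. Defaults state a
    16x64x64 grid (divisible by 8 in-plane for the tiny network) with voxel
    spacing (4, 0.72, 0.72) mm, semi-axes that keep the kidney inside the
    grid at any jittered pose, and the ``dw_like`` high-contrast preset.
    """

    n_subjects: int = 12
    grid: Tuple[int, int, int] = (16, 64, 64)
    spacing: Tuple[float, float, float] = (4.0, 0.72, 0.72)
    # geometry defaults scale with the grid; at 16x64x64 they resolve to
    # semi-axes ((3.5, 5.5), (10, 14), (8, 12)) and jitter (1, 4, 4)
    semi_axes_range: Tuple[AxisRange, AxisRange, AxisRange] | None = None
    rotation_range: float = 20.0  # in-plane rotation, degrees
    center_jitter: Tuple[float, float, float] | None = None
    fg_mean: float = 200.0
    bg_mean: float = 50.0
    noise_sd: float = 15.0
    bias_amplitude: float = 0.2
    concavity: float = 0.3  # relative size of the bean-shape dent; 0 disables
    modality_preset: str | None = "dw_like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality_preset is not None:
            if self.modality_preset not in MODALITY_PRESETS:
                raise ValueError(
                    f"unknown preset {self.modality_preset!r}; "
                    f"choose from {sorted(MODALITY_PRESETS)}"
                )
            self.fg_mean, self.bg_mean, self.noise_sd = MODALITY_PRESETS[self.modality_preset]
        d, h, w = self.grid
        if self.center_jitter is None:
            self.center_jitter = (d / 16.0, h / 16.0, w / 16.0)
        if self.semi_axes_range is None:
            ranges = []
            for size, jit, (f_lo, f_hi) in zip(
                self.grid,
                self.center_jitter,
                ((0.21875, 0.34375), (0.15625, 0.21875), (0.125, 0.1875)),
            ):
                # keep the jittered ellipsoid strictly inside the grid
                hi = min(f_hi * size, size / 2.0 - 1.0 - jit)
                ranges.append((min(f_lo * size, hi), hi))
            self.semi_axes_range = tuple(ranges)


def _subject_rng(cfg: PhantomConfig, index: int) -> np.random.Generator:
    # seed sequence keyed on (cohort seed, subject index): deterministic and
    # independent per subject
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(index)]))


def _sample_pose(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    semi = [rng.uniform(lo, hi) for lo, hi in cfg.semi_axes_range]
    jitter = [rng.uniform(-j, j) for j in cfg.center_jitter]
    center = [g / 2.0 + j for g, j in zip(cfg.grid, jitter)]
    angle = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
    dent_side = rng.choice([-1.0, 1.0])
    return {
        "semi_axes": tuple(semi),
        "center": tuple(center),
        "angle_deg": float(angle),
        "dent_side": float(dent_side),
    }


def _ellipsoid_mask(
    grid: Tuple[int, int, int],
    center: Tuple[float, float, float],
    semi: Tuple[float, float, float],
    angle_deg: float,
    concavity: float,
    dent_side: float,
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(grid[0], dtype=np.float64),
        np.arange(grid[1], dtype=np.float64),
        np.arange(grid[2], dtype=np.float64),
        indexing="ij",
    )
    dz = zz - center[0]
    dy = yy - center[1]
    dx = xx - center[2]
    # analytic in-plane rotation of the coordinate frame: exact binary mask,
    # no interpolation artifacts
    th = np.deg2rad(angle_deg)
    ry = np.cos(th) * dy - np.sin(th) * dx
    rx = np.sin(th) * dy + np.cos(th) * dx
    az, ay, ax = semi
    body = (dz / az) ** 2 + (ry / ay) ** 2 + (rx / ax) ** 2 <= 1.0
    if concavity > 0:
        # a smaller ellipsoid biting into one in-plane side produces the
        # renal-hilum-like dent; it is placed at the boundary so the mask
        # stays a single connected component
        dent_center_y = dent_side * ay
        dent = (
            (dz / (concavity * az * 2.0)) ** 2
            + ((ry - dent_center_y) / (concavity * ay * 2.0)) ** 2
            + (rx / (concavity * ax * 2.0)) ** 2
            <= 1.0
        )
        body &= ~dent
    return body


def _bias_field(
    grid: Tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative inhomogeneity: 1 + amplitude * low-freq cosines."""
    if amplitude == 0:
        return np.ones(grid, dtype=np.float64)
    zz, yy, xx = np.meshgrid(
        np.linspace(0, 1, grid[0]),
        np.linspace(0, 1, grid[1]),
        np.linspace(0, 1, grid[2]),
        indexing="ij",
    )
    n_modes = int(rng.integers(2, 4))
    fieldsum = np.zeros(grid, dtype=np.float64)
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        fieldsum += np.cos(2 * np.pi * freq[0] * zz + phase[0]) * np.cos(
            2 * np.pi * freq[1] * yy + phase[1]
        ) * np.cos(2 * np.pi * freq[2] * xx + phase[2])
    fieldsum /= max(np.abs(fieldsum).max(), 1e-12)
    return 1.0 + amplitude * fieldsum


def make_subject(cfg: PhantomConfig, index: int) -> Tuple[GridVolume, BinaryMask]:
    """One deterministic (volume, mask) pair for subject ``index``.

    The mask is a rotated, jittered, optionally dented ellipsoid; the image
    is a two-level field (fg/bg means) modulated by the multiplicative bias
    field plus additive Gaussian noise. Identical (seed, index) always
    yields the identical pair. Raises if the sampled pose would push the
    object outside the grid.
    """
    rng = _subject_rng(cfg, index)
    pose = _sample_pose(cfg, rng)
    semi, center = pose["semi_axes"], pose["center"]
    for axis in range(3):
        if center[axis] - semi[axis] < 0 or center[axis] + semi[axis] > cfg.grid[axis] - 1:
            raise ValueError(
                f"subject {index}: ellipsoid exceeds grid on axis {axis} "
                f"(center {center[axis]:.1f}, semi-axis {semi[axis]:.1f}, "
                f"extent {cfg.grid[axis]})"
            )
    mask = _ellipsoid_mask(
        cfg.grid, center, semi, pose["angle_deg"], cfg.concavity, pose["dent_side"]
    )

    fg = np.full(cfg.grid, cfg.fg_mean, dtype=np.float64)
    if cfg.modality_preset == "bold_like":
        # crude multi-echo decay surrogate: foreground signal fades along z
        decay = 1.0 - 0.25 * (np.arange(cfg.grid[0]) / max(cfg.grid[0] - 1, 1))
        fg *= decay[:, None, None]
    img = np.where(mask, fg, cfg.bg_mean)
    img = img * _bias_field(cfg.grid, cfg.bias_amplitude, rng)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=cfg.grid)

    vol = GridVolume(
        data=img.astype(np.float32), spacing=cfg.spacing, origin_tag=f"phantom_{index:03d}"
    )
    return vol, BinaryMask(data=mask.astype(np.uint8), spacing=cfg.spacing)


def make_cohort(
    cfg: PhantomConfig,
) -> Tuple[List[Tuple[GridVolume, BinaryMask]], pd.DataFrame]:
    """A cohort of subjects plus a manifest of per-subject pose parameters."""
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    pairs = []
    rows = []
    for i in range(cfg.n_subjects):
        pose = _sample_pose(cfg, _subject_rng(cfg, i))
        vol, mask = make_subject(cfg, i)
        pairs.append((vol, mask))
        coords = np.argwhere(mask.data)
        cz, cy, cx = coords.mean(axis=0)
        rows.append(
            {
                "subject": i,
                "semi_z": pose["semi_axes"][0],
                "semi_y": pose["semi_axes"][1],
                "semi_x": pose["semi_axes"][2],
                "center_z": pose["center"][0],
                "center_y": pose["center"][1],
                "center_x": pose["center"][2],
                "angle_deg": pose["angle_deg"],
                "dent_side": pose["dent_side"],
                "centroid_z": cz,
                "centroid_y": cy,
                "centroid_x": cx,
                "volume_voxels": int(mask.data.sum()),
            }
        )
    return pairs, pd.DataFrame(rows)
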