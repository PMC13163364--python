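"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain triple/quadruple loops over voxels,
deliberately sharing no code with the package, so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def oracle_band_partition(mask: np.ndarray, n_bands: int, thickness: int) -> np.ndarray:
    """Per-slice distance-to-boundary bands by exhaustive pairwise search."""
    mask = mask.astype(bool)
    out = np.zeros(mask.shape, dtype=int)
    D, H, W = mask.shape
    for z in range(D):
        sl = mask[z]
        if not sl.any():
            continue
        boundary = []
        for y in range(H):
            for x in range(W):
                if not sl[y, x]:
                    continue
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < H and 0 <= nx < W) or not sl[ny, nx]:
                        boundary.append((y, x))
                        break
        for y in range(H):
            for x in range(W):
                d = min(math.hypot(y - by, x - bx) for by, bx in boundary)
                band = max(1, math.ceil(d / thickness))
                out[z, y, x] = min(band, n_bands)
    return out


def oracle_phi(vol: np.ndarray, bands: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood response by exhaustive loops; returns (phi, count)."""
    D, H, W = vol.shape
    phi = np.zeros((D, H, W), dtype=np.int64)
    count = np.zeros((D, H, W), dtype=np.int64)
    for z in range(D):
        for y in range(H):
            for x in range(W):
                b = bands[z, y, x]
                if b == 0:
                    continue
                for k in (z - 1, z, z + 1):
                    if not (0 <= k < D):
                        continue
                    for dy in range(-radius, radius + 1):
                        for dx in range(-radius, radius + 1):
                            ny, nx = y + dy, x + dx
                            if not (0 <= ny < H and 0 <= nx < W):
                                continue
                            if bands[k, ny, nx] == b:
                                phi[z, y, x] += vol[k, ny, nx]
                                count[z, y, x] += 1
    return phi, count


def oracle_phi_levels(vol: np.ndarray, bands: np.ndarray, radius: int) -> np.ndarray:
    phi, count = oracle_phi(vol, bands, radius)
    lev = np.zeros(vol.shape, dtype=np.int64)
    nz = count > 0
    lev[nz] = np.rint(phi[nz] / count[nz]).astype(np.int64)
    return lev


def oracle_histograms(
    pairs, n_bands: int, thickness: int, radius: int, levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive accumulation of per-band fg/bg response histograms."""
    hist_fg = np.zeros((n_bands, levels), dtype=np.int64)
    hist_bg = np.zeros((n_bands, levels), dtype=np.int64)
    for vol, mask in pairs:
        bands = oracle_band_partition(mask, n_bands, thickness)
        lev = oracle_phi_levels(vol, bands, radius)
        D, H, W = vol.shape
        for z in range(D):
            for y in range(H):
                for x in range(W):
                    b = bands[z, y, x]
                    if b == 0:
                        continue
                    lv = min(max(int(lev[z, y, x]), 0), levels - 1)
                    if mask[z, y, x]:
                        hist_fg[b - 1, lv] += 1
                    else:
                        hist_bg[b - 1, lv] += 1
    return hist_fg, hist_bg


def oracle_likelihood(
    hist_fg: np.ndarray, hist_bg: np.ndarray, level: int, band: int, delta_max: int = 3
) -> float:
    """Ratio with symmetric delta-expansion fallback, per the stated rule."""
    fg, bg = hist_fg[band - 1], hist_bg[band - 1]
    levels = len(fg)
    k, b = int(fg[level]), int(bg[level])
    if k + b > 0:
        return k / (k + b)
    for delta in range(1, delta_max + 1):
        k = b = 0
        for j in (level - delta, level + delta):
            if 0 <= j < levels:
                k += int(fg[j])
                b += int(bg[j])
        if k + b > 0:
            return k / (k + b)
    return 0.5


def oracle_boundary(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with a face-adjacent background neighbor (edges = bg)."""
    D, H, W = mask.shape
    out = []
    for z in range(D):
        for y in range(H):
            for x in range(W):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if not (0 <= nz < D and 0 <= ny < H and 0 <= nx < W) or not mask[nz, ny, nx]:
                        out.append((z, y, x))
                        break
    return out


def oracle_surface_distances(
    pred: np.ndarray, ref: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Pooled symmetric nearest-boundary distances by exhaustive pairing."""
    bp = np.array(oracle_boundary(pred), dtype=float) * spacing
    br = np.array(oracle_boundary(ref), dtype=float) * spacing
    d_pr = [min(np.linalg.norm(p - r) for r in br) for p in bp]
    d_rp = [min(np.linalg.norm(r - p) for p in bp) for r in br]
    return np.sort(np.array(d_pr + d_rp))


def oracle_wilcoxon_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors.

    Tied |d| receive average ranks. Two-sided p = 2 * min(P(W+ <= w),
    P(W+ >= w)) capped at 1, the standard exact convention.
    """
    d = np.asarray(diffs, dtype=float)
    assert not np.any(d == 0), "oracle assumes no zero differences"
    n = len(d)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(float(sum(r for s, r in zip(signs, ranks) if s)))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def oracle_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook recursion."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        k = m - rank_from_top  # 1-based rank of this p-value
        val = min(prev, pvals[idx] * m / k)
        adj[idx] = val
        prev = val
    return adj
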