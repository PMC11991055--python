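"""Contrast enhancement of the V (brightness) plane.

Three enhancers are provided, all operating on a single 8-bit gray plane
(the V component of the HSV image; hue and saturation pass through
untouched):

* :func:`global_equalize` — classic global histogram equalization (GHE),
  mapping each level through the image CDF.
* :func:`improved_clahe` — tile-wise contrast-limited equalization whose
  clip limit adapts to tile brightness, whose clipped-off pixel mass is
  redistributed with sigmoid weights derived from the local histogram, and
  whose tile seams are blended with a 5×5 quartic interpolation kernel.
* :func:`fuse_global_local` / :func:`clgce` — an adaptive convex
  combination of the two, weighted by a sigmoid in the image's mean
  brightness and brightness spread, so bright low-contrast images lean on
  the global map and dark detailed images on the local one.

All integer rounding at stage boundaries is round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .raster_core import validate_plane

__all__ = [
    "FusionParams",
    "ClaheParams",
    "global_equalize",
    "equalize_map",
    "adjust_clip_limit",
    "clip_and_redistribute",
    "tile_remap",
    "bicubic_kernel_weights",
    "bicubic_reconstruct",
    "improved_clahe",
    "fusion_weight",
    "fuse_global_local",
    "clgce",
]

L_LEVELS = 256


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class ClaheParams:
    """Tunables of the improved tile-wise equalization.

    ``base`` guarantees some contrast limiting even for bright tiles;
    ``scale`` raises the clip limit for dark tiles (counts per brightness
    level below ``threshold``); ``alpha_smooth`` sets the steepness of the
    sigmoid redistribution weights; ``invert_weights`` makes histogram
    valleys (sparse bins) receive the larger share of the clipped mass.
    """

    tile_grid: tuple[int, int] = (8, 8)  # (rows, cols) of tiles
    base: float = 4.0
    scale: float = 0.1
    threshold: float = 128.0
    alpha_smooth: float = 0.05
    invert_weights: bool = True
    weight_threshold: float | None = None  # None -> mean bin count of the tile


@dataclass(frozen=True)
class FusionParams:
    """Sigmoid fusion weight: α = 1/(1+exp(−k(L_avg−L0) − m(σ−σ0)))."""

    k: float = 0.05
    m: float = 0.05
    l0: float = 128.0
    sigma0: float = 50.0
    clahe: ClaheParams = field(default_factory=ClaheParams)


# ---------------------------------------------------------------------------
# Global histogram equalization


def equalize_map(plane: np.ndarray) -> np.ndarray:
    """The 256-entry GHE level map ``G(r) = round((L−1)·CDF(r))``."""
    plane = validate_plane(plane)
    counts = np.bincount(np.asarray(plane, dtype=np.uint8).ravel(), minlength=L_LEVELS)
    cdf = np.cumsum(counts) / counts.sum()
    return _round_half_up((L_LEVELS - 1) * cdf).astype(np.uint8)


def global_equalize(plane: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit plane."""
    lut = equalize_map(plane)
    return lut[np.asarray(plane, dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Improved CLAHE building blocks


def adjust_clip_limit(l_avg: float, base: float, scale: float, threshold: float) -> float:
    """Brightness-adaptive clip limit ``Base + Scale·max(0, Threshold − L_avg)``.

    Darker tiles get a higher ceiling (stronger enhancement); tiles at or
    above the brightness threshold keep the floor ``Base``.
    """
    if base <= 0:
        raise ValueError(f"Base must be positive, got {base}")
    if scale < 0:
        raise ValueError(f"Scale must be non-negative, got {scale}")
    return base + scale * max(0.0, threshold - l_avg)


def clip_and_redistribute(
    h_r: np.ndarray,
    clip_limit: float,
    alpha_smooth: float,
    weight_threshold: float,
    invert_weights: bool = True,
) -> np.ndarray:
    """Clip the histogram at *clip_limit* and redistribute the excess.

    Bins are weighted with a logistic curve in their own count,
    ``w(i) = 1/(1+exp(∓α(h(i)−T_w)))`` (sign flipped when
    *invert_weights*, so valleys receive the larger weights), and the
    clipped-off mass is shared proportionally.  The fractional residue is
    then swept bin-by-bin, one count at a time, until the total pixel count
    is conserved exactly.
    """
    h_r = np.asarray(h_r, dtype=np.int64)
    if (h_r < 0).any():
        raise ValueError("histogram counts must be non-negative")
    if clip_limit < 1:
        raise ValueError(f"clip limit must be ≥ 1, got {clip_limit}")
    h_clipped = np.minimum(h_r, int(np.floor(clip_limit)))
    excess = int((h_r - h_clipped).sum())
    if excess == 0:
        return h_clipped
    arg = alpha_smooth * (h_r.astype(np.float64) - weight_threshold)
    if invert_weights:
        arg = -arg
    w = 1.0 / (1.0 + np.exp(-arg))
    share = excess * w / w.sum()
    add = np.floor(share).astype(np.int64)
    h_final = h_clipped + add
    residue = excess - int(add.sum())
    if residue > 0:  # traverse the bins again, one count at a time
        order = np.arange(h_r.size)
        extra = np.zeros(h_r.size, dtype=np.int64)
        idx = order[np.arange(residue) % h_r.size]
        np.add.at(extra, idx, 1)
        h_final = h_final + extra
    return h_final


def tile_remap(h_final: np.ndarray, tile: np.ndarray) -> np.ndarray:
    """Map tile pixels through the redistributed histogram's CDF.

    ``CDF_norm(i) = (CDF(i) − CDF_min)/(n − CDF_min) · (L−1)`` with
    ``CDF_min`` the smallest nonzero CDF value.  A constant tile (where
    CDF_min equals the pixel count, making the mapping 0/0) maps to itself.
    """
    h_final = np.asarray(h_final, dtype=np.int64)
    n = int(h_final.sum())
    if n == 0:
        raise ValueError("all-zero histogram")
    cdf = np.cumsum(h_final)
    cdf_min = int(cdf[cdf > 0][0])
    if cdf_min == n:  # degenerate single-level tile: identity
        return np.asarray(tile, dtype=np.uint8).copy()
    lut = _round_half_up((cdf - cdf_min) / (n - cdf_min) * (L_LEVELS - 1))
    lut = np.clip(lut, 0, L_LEVELS - 1).astype(np.uint8)
    return lut[np.asarray(tile, dtype=np.uint8)]


def bicubic_kernel_weights() -> np.ndarray:
    """Normalized 5×5 blending table ``W(i,j) ∝ K(i/2, j/2)``, K(u,v)=(1−u⁴)(1−v⁴).

    K vanishes at |u| = 1, so the outer ring (offsets ±2) contributes
    nothing; the table is normalized to unit sum so constant regions pass
    through unchanged.
    """
    off = np.arange(-2, 3) / 2.0
    k1 = 1.0 - off**4
    w = np.outer(k1, k1)
    return w / w.sum()


def bicubic_reconstruct(plane: np.ndarray) -> np.ndarray:
    """Blend tile seams with the normalized 5×5 quartic kernel (edge-replicated)."""
    w = bicubic_kernel_weights()
    out = ndi.correlate(np.asarray(plane, dtype=np.float64), w, mode="nearest")
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


def _tile_edges(length: int, n_tiles: int) -> np.ndarray:
    return np.linspace(0, length, n_tiles + 1).astype(int)


def improved_clahe(plane: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Brightness-adaptive, smoothing-redistributed tile equalization.

    The plane is divided into a grid of tiles; each tile is equalized with
    its own clip-limited, redistributed histogram; seams between tiles are
    then blended with the 5×5 quartic kernel.
    """
    params = params or ClaheParams()
    plane = validate_plane(plane)
    plane = np.asarray(plane, dtype=np.uint8)
    h, w = plane.shape
    rows, cols = params.tile_grid
    rows = max(1, min(rows, h // 8))
    cols = max(1, min(cols, w // 8))
    if h // rows < 8 or w // cols < 8:
        raise ValueError(
            f"tile grid {params.tile_grid} gives tiles smaller than 8×8 on a {w}x{h} plane"
        )
    ye = _tile_edges(h, rows)
    xe = _tile_edges(w, cols)
    out = np.empty_like(plane)
    for i in range(rows):
        for j in range(cols):
            tile = plane[ye[i] : ye[i + 1], xe[j] : xe[j + 1]]
            l_avg = float(tile.mean())
            clip = adjust_clip_limit(l_avg, params.base, params.scale, params.threshold)
            h_r = np.bincount(tile.ravel(), minlength=L_LEVELS)
            w_thr = (
                params.weight_threshold
                if params.weight_threshold is not None
                else h_r.mean()
            )
            h_final = clip_and_redistribute(
                h_r, max(clip, 1.0), params.alpha_smooth, w_thr, params.invert_weights
            )
            out[ye[i] : ye[i + 1], xe[j] : xe[j + 1]] = tile_remap(h_final, tile)
    return bicubic_reconstruct(out)


# ---------------------------------------------------------------------------
# Adaptive global/local fusion (CLGCE)


def fusion_weight(l_avg: float, sigma: float, params: FusionParams) -> float:
    """α = 1/(1+exp(−k(L_avg−L0) − m(σ−σ0))); strictly inside (0, 1)."""
    z = params.k * (l_avg - params.l0) + params.m * (sigma - params.sigma0)
    return float(1.0 / (1.0 + np.exp(-z)))


def fuse_global_local(
    z_global: np.ndarray,
    z_local: np.ndarray,
    l_avg: float,
    sigma: float,
    params: FusionParams | None = None,
) -> tuple[np.ndarray, float]:
    """Convex per-pixel blend ``Z = α·Z_Global + (1−α)·Z_Local``, rounded to 8 bits."""
    params = params or FusionParams()
    alpha = fusion_weight(l_avg, sigma, params)
    z = alpha * np.asarray(z_global, dtype=np.float64) + (1.0 - alpha) * np.asarray(
        z_local, dtype=np.float64
    )
    return np.clip(_round_half_up(z), 0, 255).astype(np.uint8), alpha


def clgce(plane: np.ndarray, params: FusionParams | None = None) -> np.ndarray:
    """Adaptive global–local contrast enhancement of a V plane.

    Runs GHE and the improved tile equalization on the same plane, then
    fuses them with a weight driven by the plane's mean brightness and
    brightness standard deviation.
    """
    params = params or FusionParams()
    plane = validate_plane(plane)
    arr = np.asarray(plane, dtype=np.uint8)
    z_g = global_equalize(arr)
    z_l = improved_clahe(arr, params.clahe)
    l_avg = float(arr.mean())
    sigma = float(arr.astype(np.float64).std())
    fused, _ = fuse_global_local(z_g, z_l, l_avg, sigma, params)
    return fused
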