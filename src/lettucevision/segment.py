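"""Multidimensional segmentation of deficient tissue.

Three cooperating stages delimit discolored (nutrient-deficient) tissue in
an enhanced HSV canopy image:

1. **HSV band thresholding** — each plane is binarized against a
   [lo, hi] interval (three independent 1-D problems) and the plane masks
   are ANDed; this coarse mask finds the characteristic lesion colors.
2. **Edge delimitation** — the multi-directional adaptive Canny detector
   run on the V plane, restricted to a dilated neighborhood of the coarse
   mask, sharpens the lesion boundaries.
3. **Gradient-guided adaptive thresholding** — the image is divided into
   blocks; each block's threshold is the distance-weighted mean intensity
   (weights 1/(1+d) from the block center) and pixels whose normalized
   gradient magnitude exceeds their block threshold are marked foreground.

The fusion keeps the coarse mask's interior, replaces its boundary with
the morphologically closed union of the edge and gradient stages, fills
holes, and never grows beyond the dilated coarse mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk

from . import edges as edges_mod

__all__ = [
    "HsvBands",
    "BlockGrid",
    "SegmentParams",
    "hsv_band_threshold",
    "block_weights",
    "adaptive_threshold",
    "block_thresholds",
    "gradient_guided_segment",
    "multidimensional_segment",
    "HUE_BAND_PRESETS",
]

# Characteristic-color hue bands on the package's 0-255 hue wheel.
# These presets are calibration knobs of the artifact:
#   nband — yellowing/chlorosis (nitrogen),
#   pband — dark purplish patches (phosphorus),
#   kband — brown/orange marginal scorch (potassium).
HUE_BAND_PRESETS: dict[str, tuple[int, int]] = {
    "nband": (25, 60),
    "pband": (175, 220),
    "kband": (4, 24),
}


@dataclass(frozen=True)
class HsvBands:
    """Per-plane [lo, hi] thresholds (0-255 scale for every plane)."""

    hue: tuple[float, float] = (0, 255)
    sat: tuple[float, float] = (0, 255)
    val: tuple[float, float] = (0, 255)

    def __post_init__(self):
        for name, (lo, hi) in (("hue", self.hue), ("sat", self.sat), ("val", self.val)):
            if lo > hi:
                raise ValueError(f"inverted {name} band [{lo}, {hi}]")


@dataclass(frozen=True)
class SegmentParams:
    block_size: int = 16
    dilate_radius: int = 5  # growth allowance around the coarse mask
    close_radius: int = 3  # boundary-closing structuring element
    hole_max_area: int = 64  # only holes up to this size are filled
    min_area: int = 16  # components below this size are dropped as speckle
    canny_ratio: float = 0.4
    canny_sigma: float = 1.0


def hsv_band_threshold(hsv: np.ndarray, bands: HsvBands) -> np.ndarray:
    """AND of the three per-plane interval masks; boolean output."""
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected HSV image of shape (H, W, 3), got {hsv.shape}")
    mask = np.ones(hsv.shape[:2], dtype=bool)
    for plane, (lo, hi) in zip(range(3), (bands.hue, bands.sat, bands.val)):
        p = hsv[:, :, plane]
        mask &= (p >= lo) & (p <= hi)
    return mask


def block_weights(shape: tuple[int, int]) -> np.ndarray:
    """Distance weights ``w = 1/(1+d)`` to the block center for one block.

    The center of an h×w block is ((h−1)/2, (w−1)/2); d is the Euclidean
    pixel distance, so w = 1 exactly at the center and decays with radius.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    return 1.0 / (1.0 + d)


def adaptive_threshold(block: np.ndarray) -> float:
    """Distance-weighted mean intensity ``Σ w·I / Σ w`` of one block."""
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValueError("empty block")
    w = block_weights(block.shape)
    return float((w * block).sum() / w.sum())


def _block_slices(length: int, size: int):
    edges = list(range(0, length, size)) + [length]
    # merge a trailing sliver (< size/2) into the previous block
    if len(edges) > 2 and edges[-1] - edges[-2] < size // 2:
        edges.pop(-2)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class BlockGrid:
    """Rectangular block decomposition with per-block adaptive thresholds."""

    row_slices: list = field(default_factory=list)
    col_slices: list = field(default_factory=list)
    thresholds: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))


def block_thresholds(intensity: np.ndarray, block_size: int = 16) -> BlockGrid:
    """Adaptive thresholds for every block of the intensity plane."""
    arr = np.asarray(intensity, dtype=np.float64)
    rs = _block_slices(arr.shape[0], block_size)
    cs = _block_slices(arr.shape[1], block_size)
    t = np.empty((len(rs), len(cs)))
    for i, r in enumerate(rs):
        for j, c in enumerate(cs):
            t[i, j] = adaptive_threshold(arr[r, c])
    return BlockGrid(row_slices=rs, col_slices=cs, thresholds=t)


def gradient_guided_segment(magnitude: np.ndarray, grid: BlockGrid) -> np.ndarray:
    """Foreground iff the pixel's gradient magnitude exceeds its block threshold."""
    mag = np.asarray(magnitude, dtype=np.float64)
    out = np.zeros(mag.shape, dtype=bool)
    for i, r in enumerate(grid.row_slices):
        for j, c in enumerate(grid.col_slices):
            out[r, c] = mag[r, c] > grid.thresholds[i, j]
    return out


def _normalize_magnitude(mag: np.ndarray) -> np.ndarray:
    """Min–max normalize a gradient-magnitude plane to [0, 255].

    The gradient is compared against intensity-derived block thresholds,
    so both operands must share the 8-bit scale.
    """
    mag = np.asarray(mag, dtype=np.float64)
    lo, hi = float(mag.min()), float(mag.max())
    if hi == lo:
        return np.zeros_like(mag)
    return (mag - lo) / (hi - lo) * 255.0


def multidimensional_segment(
    hsv: np.ndarray,
    bands: "HsvBands | Sequence[HsvBands]",
    params: SegmentParams | None = None,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Three-stage deficient-tissue segmentation of an enhanced HSV image.

    *bands* may be a single band triple or a sequence of them (one per
    characteristic lesion color); the coarse mask is the union.  *roi*
    optionally restricts the search to a region of interest (typically the
    plant canopy mask — deficient tissue is plant tissue by definition).
    Returns a boolean mask.  An empty coarse (stage-1) mask produces an
    empty result with a warning rather than an error — a healthy canopy is
    a legitimate input.
    """
    params = params or SegmentParams()
    if isinstance(bands, HsvBands):
        bands = [bands]
    coarse = np.zeros(np.asarray(hsv).shape[:2], dtype=bool)
    for b in bands:
        coarse |= hsv_band_threshold(hsv, b)
    if roi is not None:
        coarse &= np.asarray(roi, dtype=bool)
    if not coarse.any():
        warnings.warn("no pixels matched the HSV bands; returning an empty mask")
        return coarse
    v = np.asarray(hsv[:, :, 2], dtype=np.float64)
    allowed = ndi.binary_dilation(coarse, structure=disk(params.dilate_radius))
    # edge/gradient refinements act on the coarse mask's boundary band only
    band_zone = ndi.binary_dilation(coarse, structure=disk(2)) & ~ndi.binary_erosion(
        coarse, structure=disk(2)
    )

    # stage 2: edge delimitation near the coarse region
    edge_map = edges_mod.improved_canny(v, params.canny_ratio, params.canny_sigma)

    # stage 3: gradient-guided refinement on the normalized magnitude
    field_ = edges_mod.directional_gradients(
        ndi.gaussian_filter(v, params.canny_sigma, truncate=2.0, mode="nearest")
        if params.canny_sigma > 0
        else v
    )
    mag, _ = edges_mod.combine_gradients(field_)
    grid = block_thresholds(v, params.block_size)
    fg = gradient_guided_segment(_normalize_magnitude(mag), grid)

    refine = (edge_map | fg) & band_zone
    candidate = ndi.binary_closing(coarse | refine, structure=disk(params.close_radius))
    fused = _fill_small_holes(candidate, params.hole_max_area)
    fused &= allowed
    if roi is not None:
        fused &= np.asarray(roi, dtype=bool)
    return _drop_speckle(fused, params.min_area)


def _fill_small_holes(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Fill only enclosed holes up to *max_area* pixels.

    Unconditional hole filling would flood the entire interior enclosed by
    ring-shaped lesions (e.g. marginal potassium scorch around the whole
    rosette); large enclosed regions are healthy tissue, not holes.
    """
    filled = ndi.binary_fill_holes(mask)
    holes = filled & ~mask
    if not holes.any():
        return mask
    labels, n = ndi.label(holes)
    sizes = np.bincount(labels.ravel())
    small = np.zeros(n + 1, dtype=bool)
    small[1:] = sizes[1:] <= max_area
    return mask | small[labels]


def _drop_speckle(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components smaller than *min_area* pixels."""
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_area
    return keep[labels]
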