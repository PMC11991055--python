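"""Multi-directional gradient, adaptive-threshold Canny edge detection.

The detector extends the classic two-kernel Sobel step to eight compass
orientations (0°, 45°, …, 315°), combines them into one magnitude by
root-sum-of-squares and one direction via the sine/cosine projections,
thins ridges with linearly interpolated non-maximum suppression, derives
the dual hysteresis thresholds automatically from the 95th percentile of
the nonzero gradient magnitudes, and links weak edges to strong ones over
8-connectivity.

Orientation convention: angles are measured counter-clockwise from the +x
(column) axis with 90° pointing *up* the image (toward smaller row
indices), matching the compass kernels below.  Because the 180°-rotated
kernels are exact negations, the combined magnitude equals √2 times the
magnitude over the first four orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "KERNEL_ANGLES",
    "kernel_bank",
    "directional_gradients",
    "combine_gradients",
    "nms_interpolated",
    "auto_thresholds",
    "ThresholdPair",
    "hysteresis_link",
    "improved_canny",
]

KERNEL_ANGLES = (0, 45, 90, 135, 180, 225, 270, 315)

# classic compass-Sobel bank; 90° responds positively to intensity
# increasing upward (toward row 0), 0° to intensity increasing rightward.
_K0 = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
_K45 = np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=np.int64)
_K90 = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.int64)
_K135 = np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]], dtype=np.int64)


def kernel_bank() -> dict[int, np.ndarray]:
    """The eight 3×3 compass kernels, keyed by angle in degrees."""
    first = {0: _K0, 45: _K45, 90: _K90, 135: _K135}
    bank = dict(first)
    for angle, k in first.items():
        bank[angle + 180] = -k
    return bank


def directional_gradients(plane: np.ndarray) -> dict[int, np.ndarray]:
    """Correlate the plane with every compass kernel (edge-replicated border)."""
    arr = np.asarray(plane, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"need a 2-D plane of at least 3×3, got shape {arr.shape}")
    return {
        angle: ndi.correlate(arr, k.astype(np.float64), mode="nearest")
        for angle, k in kernel_bank().items()
    }


def combine_gradients(field: dict[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Total magnitude ``G = √Σ g_θ²`` and direction ``atan2(Σ g sinθ, Σ g cosθ)``.

    Pixels with zero combined gradient get direction 0.
    """
    mags = np.stack([field[a] for a in KERNEL_ANGLES])
    g = np.sqrt((mags**2).sum(axis=0))
    rad = np.deg2rad(np.array(KERNEL_ANGLES, dtype=np.float64))
    sy = np.tensordot(np.sin(rad), mags, axes=1)
    sx = np.tensordot(np.cos(rad), mags, axes=1)
    theta = np.arctan2(sy, sx)
    theta[(sx == 0) & (sy == 0)] = 0.0
    return g, theta


def _octant_interpolants(mag_p: np.ndarray, theta: np.ndarray):
    """Interpolated magnitudes f(m1), f(m2) on the gradient line at each pixel.

    *mag_p* is the magnitude padded by one replicated ring; neighbors use
    the a0..a8 naming of a 3×3 window (a0 top-left, a4 center, row-major)
    with "up" = smaller row index.  The direction is folded to [0°, 180°)
    and split into four interpolation cases; the blend weight is |tanθ| in
    the near-horizontal cases and |cotθ| in the near-vertical ones, always
    in [0, 1].
    """
    a0 = mag_p[:-2, :-2]
    a1 = mag_p[:-2, 1:-1]
    a2 = mag_p[:-2, 2:]
    a3 = mag_p[1:-1, :-2]
    a5 = mag_p[1:-1, 2:]
    a6 = mag_p[2:, :-2]
    a7 = mag_p[2:, 1:-1]
    a8 = mag_p[2:, 2:]

    ang = np.rad2deg(theta) % 180.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(np.tan(theta))
        ct = np.where(t > 0, 1.0 / t, np.inf)
    f1 = np.empty_like(theta)
    f2 = np.empty_like(theta)

    m = ang < 45.0  # gradient mostly +x, tilted up-right
    w = np.clip(np.where(m, t, 0.0), 0.0, 1.0)
    f1[m] = (w * a2 + (1.0 - w) * a5)[m]
    f2[m] = (w * a6 + (1.0 - w) * a3)[m]

    m = (ang >= 45.0) & (ang < 90.0)  # mostly up, tilted right
    w = np.clip(np.where(m, ct, 0.0), 0.0, 1.0)
    f1[m] = (w * a2 + (1.0 - w) * a1)[m]
    f2[m] = (w * a6 + (1.0 - w) * a7)[m]

    m = (ang >= 90.0) & (ang < 135.0)  # mostly up, tilted left
    w = np.clip(np.where(m, ct, 0.0), 0.0, 1.0)
    f1[m] = (w * a0 + (1.0 - w) * a1)[m]
    f2[m] = (w * a8 + (1.0 - w) * a7)[m]

    m = ang >= 135.0  # mostly −x, tilted up-left
    w = np.clip(np.where(m, t, 0.0), 0.0, 1.0)
    f1[m] = (w * a0 + (1.0 - w) * a3)[m]
    f2[m] = (w * a8 + (1.0 - w) * a5)[m]
    return f1, f2


def nms_interpolated(magnitude: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Non-maximum suppression with linear interpolation along the gradient.

    A pixel survives iff its magnitude is ≥ both interpolated magnitudes on
    the gradient line through it (ties kept); suppressed pixels become 0.
    """
    mag = np.asarray(magnitude, dtype=np.float64)
    mag_p = np.pad(mag, 1, mode="edge")
    f1, f2 = _octant_interpolants(mag_p, np.asarray(theta, dtype=np.float64))
    keep = (mag >= f1) & (mag >= f2)
    return np.where(keep, mag, 0.0)


@dataclass(frozen=True)
class ThresholdPair:
    high: float
    low: float


def auto_thresholds(magnitude: np.ndarray, ratio: float = 0.4) -> ThresholdPair:
    """Dual thresholds from the gradient-magnitude distribution.

    ``T_high`` is the nearest-rank 95th percentile of the *nonzero*
    magnitudes (including the zero mass would collapse the threshold on
    sparse-edge images); ``T_low = ratio · T_high``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    mags = np.asarray(magnitude, dtype=np.float64).ravel()
    nz = np.sort(mags[mags > 0])
    if nz.size == 0:
        raise ValueError("all gradient magnitudes are zero; no edges to threshold")
    rank = int(np.ceil(0.95 * nz.size))  # nearest-rank percentile
    t_high = float(nz[rank - 1])
    return ThresholdPair(high=t_high, low=ratio * t_high)


def hysteresis_link(suppressed: np.ndarray, t_high: float, t_low: float) -> np.ndarray:
    """Keep strong pixels (≥ T_high) and weak ones (≥ T_low) 8-connected to them."""
    supp = np.asarray(suppressed, dtype=np.float64)
    strong = supp >= t_high
    weak = supp >= t_low
    if not strong.any():
        return np.zeros_like(strong)
    labels, _ = ndi.label(weak, structure=np.ones((3, 3), dtype=int))
    keep = np.unique(labels[strong])
    return np.isin(labels, keep[keep > 0])


def improved_canny(
    plane: np.ndarray, ratio: float = 0.4, sigma_blur: float = 1.0
) -> np.ndarray:
    """Full detector: blur → 8-direction gradients → NMS → auto dual thresholds
    → hysteresis.  Returns a boolean edge map.

    *sigma_blur* ≤ 0 disables the Gaussian pre-smoothing (5×5 support at
    the default σ = 1).
    """
    arr = np.asarray(plane, dtype=np.float64)
    if sigma_blur > 0:
        arr = ndi.gaussian_filter(arr, sigma_blur, truncate=2.0 / sigma_blur, mode="nearest")
    field = directional_gradients(arr)
    mag, theta = combine_gradients(field)
    supp = nms_interpolated(mag, theta)
    if not (supp > 0).any():
        return np.zeros(arr.shape, dtype=bool)
    thr = auto_thresholds(supp, ratio)
    return hysteresis_link(supp, thr.high, thr.low)
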