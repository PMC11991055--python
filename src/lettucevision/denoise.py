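"""Dynamic-window histogram median filtering.

Impulse ("salt-and-pepper") noise picked up during acquisition and transfer
is removed with a median filter whose window size adapts to local image
structure: a 5×5 window is used in smooth regions (strong noise removal)
and a 3×3 window where the local variance exceeds a threshold θ, protecting
edges and leaf-vein detail.  The median itself is extracted from a 256-bin
intensity histogram maintained incrementally as the window slides — only
the pixels entering and leaving the window update the counts, so no window
is ever re-sorted.

Each color channel is filtered independently with its own histogram.
Windows are clipped at the image border (no padding), so the pixel count N
may be smaller than side² near edges; the variance and the median rank both
use the actual N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import validate_plane

__all__ = [
    "WindowStats",
    "local_variance",
    "select_window",
    "histogram_median",
    "sliding_window_medians",
    "iter_window_histograms",
    "dynamic_median_filter",
]

DEFAULT_THETA = 400.0  # variance threshold on the 8-bit intensity scale


@dataclass(frozen=True)
class WindowStats:
    """Statistics of one clipped window: mean μ, population variance, count N."""

    mean: float
    variance: float
    n_pixels: int

    # exact integer forms used for boundary-safe threshold comparison:
    # variance > θ  ⟺  N·Σx² − (Σx)²  >  θ·N²
    sum_: int = 0
    sum_sq: int = 0


def _window_bounds(x: int, y: int, side: int, width: int, height: int):
    r = side // 2
    return (max(0, y - r), min(height, y + r + 1), max(0, x - r), min(width, x + r + 1))


def local_variance(plane: np.ndarray, x: int, y: int, side: int = 5) -> WindowStats:
    """Population variance ``(1/N)·Σ(I−μ)²`` of the clipped window at (x, y)."""
    plane = validate_plane(plane)
    h, w = plane.shape
    y0, y1, x0, x1 = _window_bounds(x, y, side, w, h)
    win = plane[y0:y1, x0:x1].astype(np.int64)
    n = win.size
    s1 = int(win.sum())
    s2 = int((win * win).sum())
    mean = s1 / n
    var = (s2 - s1 * s1 / n) / n
    return WindowStats(mean=mean, variance=max(var, 0.0), n_pixels=n, sum_=s1, sum_sq=s2)


def select_window(stats: WindowStats, theta: float) -> int:
    """Window side for the median: 3 where Var > θ (detail), else 5 (smooth).

    The comparison is evaluated in exact integer arithmetic
    (``N·Σx² − (Σx)² > θ·N²``) so a variance landing exactly on θ always
    takes the 5×5 branch, independent of floating-point round-off.
    """
    if theta <= 0:
        raise ValueError(f"variance threshold theta must be positive, got {theta}")
    n = stats.n_pixels
    lhs = n * stats.sum_sq - stats.sum_ * stats.sum_
    return 3 if lhs > theta * n * n else 5


def histogram_median(counts: np.ndarray, n_pixels: int) -> int:
    """Median from a 256-bin histogram: ``min{v : C(v) ≥ n/2}``.

    The rank n/2 is treated as an exact rational (for 9 pixels the first
    level whose cumulative count reaches 4.5, i.e. 5), implemented as
    ``2·C(v) ≥ n``.
    """
    counts = np.asarray(counts)
    if n_pixels < 1 or counts.sum() != n_pixels:
        raise ValueError("histogram counts must sum to n_pixels ≥ 1")
    cum = np.cumsum(counts)
    return int(np.argmax(2 * cum >= n_pixels))


class _SlidingHistogram:
    """256-bin histogram updated only with entering/leaving pixels."""

    def __init__(self) -> None:
        self.counts = np.zeros(256, dtype=np.int64)
        self.n = 0

    def add(self, values: np.ndarray) -> None:
        np.add.at(self.counts, np.asarray(values, dtype=np.intp).ravel(), 1)
        self.n += values.size

    def remove(self, values: np.ndarray) -> None:
        np.subtract.at(self.counts, np.asarray(values, dtype=np.intp).ravel(), 1)
        self.n -= values.size
        if (self.counts < 0).any():
            raise RuntimeError("sliding histogram went negative")


def iter_window_histograms(plane: np.ndarray, side: int):
    """Yield ``(y, x, counts)`` for every window position, scanning each row
    left-to-right with a histogram updated only by the entering and leaving
    columns (serpentine-free reference of the incremental update scheme).
    """
    plane = validate_plane(np.asarray(plane, dtype=np.uint8))
    h, w = plane.shape
    r = side // 2
    for y in range(h):
        y0, y1 = max(0, y - r), min(h, y + r + 1)
        hist = _SlidingHistogram()
        hist.add(plane[y0:y1, 0 : min(w, r + 1)])
        yield y, 0, hist.counts.copy()
        for x in range(1, w):
            leave = x - r - 1
            enter = x + r
            if leave >= 0:
                hist.remove(plane[y0:y1, leave])
            if enter < w:
                hist.add(plane[y0:y1, enter])
            yield y, x, hist.counts.copy()


def _clipped_box_sums(arr: np.ndarray, side: int) -> np.ndarray:
    """Sum of *arr* over clipped side×side windows, exact in int64."""
    r = side // 2
    h, w = arr.shape
    integ = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=integ[1:, 1:])
    y = np.arange(h)
    x = np.arange(w)
    y0 = np.maximum(0, y - r)
    y1 = np.minimum(h, y + r + 1)
    x0 = np.maximum(0, x - r)
    x1 = np.minimum(w, x + r + 1)
    return (
        integ[np.ix_(y1, x1)]
        - integ[np.ix_(y0, x1)]
        - integ[np.ix_(y1, x0)]
        + integ[np.ix_(y0, x0)]
    )


def sliding_window_medians(plane: np.ndarray, side: int) -> np.ndarray:
    """Median of the clipped side×side window at every pixel.

    Row-sliding column-histogram algorithm: per-column 256-bin histograms
    are updated with the single row entering and leaving as the window
    advances one row; window histograms are then prefix-sums over columns.
    Exactly equivalent to sorting every window, without ever re-sorting.
    """
    plane = np.asarray(plane, dtype=np.uint8)
    h, w = plane.shape
    r = side // 2
    col_hist = np.zeros((w, 256), dtype=np.int32)
    # prime with rows [0, r]
    for yy in range(min(h, r + 1)):
        col_hist[np.arange(w), plane[yy]] += 1

    hi = np.minimum(np.arange(w) + r, w - 1)
    lo = np.arange(w) - r - 1  # −1 means "nothing to subtract"
    out = np.empty((h, w), dtype=np.uint8)
    for y in range(h):
        prefix = np.cumsum(col_hist, axis=0)
        win = prefix[hi].copy()
        valid = lo >= 0
        win[valid] -= prefix[lo[valid]]
        n = win.sum(axis=1)
        cum = np.cumsum(win, axis=1)
        out[y] = np.argmax(2 * cum >= n[:, None], axis=1)
        # slide down: row y−r leaves, row y+r+1 enters
        leave = y - r
        enter = y + r + 1
        if leave >= 0:
            col_hist[np.arange(w), plane[leave]] -= 1
        if enter < h:
            col_hist[np.arange(w), plane[enter]] += 1
    return out


def _side_map(plane: np.ndarray, theta: float) -> np.ndarray:
    """Per-pixel window side from the 5×5 clipped-window variance (Eq.-exact)."""
    arr = plane.astype(np.int64)
    s1 = _clipped_box_sums(arr, 5)
    s2 = _clipped_box_sums(arr * arr, 5)
    n = _clipped_box_sums(np.ones_like(arr), 5)
    lhs = (n * s2 - s1 * s1).astype(np.float64)
    return np.where(lhs > theta * (n * n), 3, 5)


def dynamic_median_filter(
    img: np.ndarray, theta: float = DEFAULT_THETA, base_side: int = 5
) -> np.ndarray:
    """Variance-adaptive histogram median filter, applied per color channel.

    For every pixel the variance of its 5×5 clipped window decides the
    median window (3×3 above θ, 5×5 otherwise); the output is the histogram
    median of the chosen window.  Identical to naive per-pixel
    sort-and-select, but computed with incrementally maintained histograms.
    """
    if theta <= 0:
        raise ValueError(f"variance threshold theta must be positive, got {theta}")
    if base_side != 5:
        raise ValueError("only the 5×5 variance window of the published rule is supported")
    img = np.asarray(img, dtype=np.uint8)
    single = img.ndim == 2
    if single:
        img = img[:, :, None]
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        ch = img[:, :, c]
        sides = _side_map(ch, theta)
        m3 = sliding_window_medians(ch, 3)
        m5 = sliding_window_medians(ch, 5)
        out[:, :, c] = np.where(sides == 3, m3, m5)
    return out[:, :, 0] if single else out
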