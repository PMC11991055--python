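"""Independent brute-force reference implementations used only by tests.

Every oracle here recomputes a quantity from first principles (explicit
loops, sorting, flood fill) without touching the vectorized production
code paths it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_window(plane: np.ndarray, x: int, y: int, side: int) -> np.ndarray:
    r = side // 2
    h, w = plane.shape
    return plane[max(0, y - r) : min(h, y + r + 1), max(0, x - r) : min(w, x + r + 1)]


def brute_median(values: np.ndarray) -> int:
    """First value whose cumulative count reaches n/2: sorted[ceil(n/2) − 1]."""
    s = np.sort(np.asarray(values).ravel())
    return int(s[math.ceil(s.size / 2) - 1])


def brute_dynamic_median(img: np.ndarray, theta: float) -> np.ndarray:
    """Per-pixel sort-based dynamic-window median, exact integer variance rule."""
    img = np.asarray(img, dtype=np.int64)
    single = img.ndim == 2
    if single:
        img = img[:, :, None]
    h, w, c = img.shape
    out = np.empty((h, w, c), dtype=np.uint8)
    for ch in range(c):
        plane = img[:, :, ch]
        for y in range(h):
            for x in range(w):
                win5 = brute_window(plane, x, y, 5)
                n = win5.size
                s1 = int(win5.sum())
                s2 = int((win5 * win5).sum())
                side = 3 if n * s2 - s1 * s1 > theta * n * n else 5
                out[y, x, ch] = brute_median(brute_window(plane, x, y, side))
    return out[:, :, 0] if single else out


def brute_nms(mag: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-pixel interpolated non-maximum suppression with explicit octants."""
    h, w = mag.shape
    pad = np.pad(mag, 1, mode="edge")
    out = np.zeros_like(mag)
    for y in range(h):
        for x in range(w):
            a = pad[y : y + 3, x : x + 3]  # a0..a8 row-major, center a[1,1]
            ang = math.degrees(theta[y, x]) % 180.0
            t = abs(math.tan(theta[y, x]))
            if ang < 45.0:
                wgt = min(t, 1.0)
                f1 = wgt * a[0, 2] + (1 - wgt) * a[1, 2]
                f2 = wgt * a[2, 0] + (1 - wgt) * a[1, 0]
            elif ang < 90.0:
                wgt = min(1.0 / t if t > 0 else float("inf"), 1.0)
                f1 = wgt * a[0, 2] + (1 - wgt) * a[0, 1]
                f2 = wgt * a[2, 0] + (1 - wgt) * a[2, 1]
            elif ang < 135.0:
                wgt = min(1.0 / t if t > 0 else float("inf"), 1.0)
                f1 = wgt * a[0, 0] + (1 - wgt) * a[0, 1]
                f2 = wgt * a[2, 2] + (1 - wgt) * a[2, 1]
            else:
                wgt = min(t, 1.0)
                f1 = wgt * a[0, 0] + (1 - wgt) * a[1, 0]
                f2 = wgt * a[2, 2] + (1 - wgt) * a[1, 2]
            if a[1, 1] >= f1 and a[1, 1] >= f2:
                out[y, x] = mag[y, x]
    return out


def brute_percentile_95(values: np.ndarray) -> float:
    """Nearest-rank 95th percentile of the nonzero values, by full sort."""
    nz = sorted(v for v in np.asarray(values).ravel() if v > 0)
    rank = math.ceil(0.95 * len(nz))
    return float(nz[rank - 1])


def brute_hysteresis(supp: np.ndarray, t_high: float, t_low: float) -> np.ndarray:
    """BFS flood fill over weak pixels seeded from strong pixels (8-connected)."""
    h, w = supp.shape
    strong = supp >= t_high
    weak = supp >= t_low
    out = np.zeros((h, w), dtype=bool)
    q = deque(zip(*np.nonzero(strong)))
    for y, x in q:
        out[y, x] = True
    q = deque(q)
    while q:
        y, x = q.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and weak[ny, nx] and not out[ny, nx]:
                    out[ny, nx] = True
                    q.append((ny, nx))
    return out


def brute_weighted_block_threshold(block: np.ndarray) -> float:
    """Distance-weighted mean by explicit per-pixel enumeration."""
    h, w = block.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    num = den = 0.0
    for y in range(h):
        for x in range(w):
            wt = 1.0 / (1.0 + math.hypot(y - cy, x - cx))
            num += wt * float(block[y, x])
            den += wt
    return num / den
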