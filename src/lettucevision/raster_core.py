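"""Image containers, color-space conversion, and file I/O shared by all stages.

Conventions used throughout the package:

* images are numpy arrays indexed ``[row, col]`` (``y`` is the row, ``x`` the
  column), 0-based, origin at the top-left;
* 8-bit RGB images are ``uint8`` arrays of shape ``(H, W, 3)``;
* gray planes are single-channel 8-bit arrays with 256 levels;
* HSV planes are kept on a common 0-255 scale so that every stage can reuse
  the same 256-bin histogram machinery.  Hue of achromatic pixels is 0 by
  convention.  In memory the HSV planes are float64 (quantization to 8 bits
  happens only when an HSV plane is written to disk), which keeps the
  RGB->HSV->RGB round trip within one intensity level per channel.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

__all__ = [
    "read_image",
    "write_image",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb565_decode",
    "validate_rgb",
    "validate_plane",
]

MIN_SIDE = 8  # minimum width/height for the windowed operators downstream


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that *img* is an 8-bit H×W×3 raster of workable size."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got dtype {img.dtype}")
    if img.shape[0] < MIN_SIDE or img.shape[1] < MIN_SIDE:
        raise ValueError(
            f"image {img.shape[1]}x{img.shape[0]} is smaller than the "
            f"{MIN_SIDE}x{MIN_SIDE} minimum required by windowed operators"
        )
    return img


def validate_plane(plane: np.ndarray) -> np.ndarray:
    """Check that *plane* is a 2-D intensity plane with values in [0, 255]."""
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got shape {plane.shape}")
    if plane.size == 0:
        raise ValueError("empty plane")
    if plane.dtype != np.uint8:
        mn, mx = float(plane.min()), float(plane.max())
        if mn < 0 or mx > 255:
            raise ValueError(f"plane values outside [0, 255]: min {mn}, max {mx}")
    return plane


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/BMP raster as an 8-bit RGB array.

    16-bit inputs are rescaled to 8 bits (``v * 255 / 65535``); an alpha
    channel, if present, is dropped; grayscale inputs are replicated to
    three channels.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image in {os.fspath(path)!r}")
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr)


def write_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write an 8-bit image (RGB or single plane) to *path*.

    Float planes (e.g. in-memory HSV) are rounded half-up and clipped to
    the 8-bit range first.
    """
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.floor(arr.astype(np.float64) + 0.5), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Hexcone RGB→HSV conversion with every plane on a 0-255 scale.

    Returns a float64 array of shape ``(H, W, 3)`` with planes (hue,
    saturation, value).  Hue 0-255 spans the full 0-360° wheel; achromatic
    pixels get hue 0 and saturation 0.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected shape (H, W, 3), got {img.shape}")
    rgb = img.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=-1)
    c = v - rgb.min(axis=-1)  # chroma
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, c / v, 0.0)
        # piecewise hue in units of 1/6 turn
        h = np.select(
            [c == 0, v == r, v == g],
            [0.0, (g - b) / c, (b - r) / c + 2.0],
            default=(r - g) / c + 4.0,
        )
    h = (h / 6.0) % 1.0
    out = np.empty(img.shape, dtype=np.float64)
    out[..., 0] = h * 255.0
    out[..., 1] = s * 255.0
    out[..., 2] = v
    return out


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; returns a uint8 RGB image."""
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected shape (H, W, 3), got {hsv.shape}")
    h = (hsv[..., 0] / 255.0) % 1.0 * 6.0
    s = np.clip(hsv[..., 1] / 255.0, 0.0, 1.0)
    v = np.clip(hsv[..., 2], 0.0, 255.0)
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


def rgb565_decode(raw: np.ndarray | bytes, width: int, height: int) -> np.ndarray:
    """Decode little-endian RGB565-packed 16-bit words into 8-bit RGB.

    The 5/6/5-bit fields are expanded to 8 bits by bit replication
    (``x5 -> x5<<3 | x5>>2``, ``x6 -> x6<<2 | x6>>4``) so that all-ones
    fields map to 255 and zero maps to 0.
    """
    if isinstance(raw, (bytes, bytearray)):
        words = np.frombuffer(raw, dtype="<u2")
    else:
        words = np.asarray(raw, dtype=np.uint16).ravel()
    if words.size != width * height:
        raise ValueError(
            f"raw buffer holds {words.size} words, expected width*height = {width * height}"
        )
    r5 = (words >> 11) & 0x1F
    g6 = (words >> 5) & 0x3F
    b5 = words & 0x1F
    r = ((r5 << 3) | (r5 >> 2)).astype(np.uint8)
    g = ((g6 << 2) | (g6 >> 4)).astype(np.uint8)
    b = ((b5 << 3) | (b5 >> 2)).astype(np.uint8)
    return np.stack([r, g, b], axis=-1).reshape(height, width, 3)
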