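"""Deterministic synthetic canopy scenes with pixel-exact ground truth.

Scenes emulate top-down views of a lettuce rosette: overlapping elliptical
leaves in green around the canvas center on a dark background, with
class-dependent discolored lesion regions of *exactly* known area fraction,
a smooth multiplicative illumination ramp, and optional salt-and-pepper
impulse noise.  Ground-truth masks are captured before noise is applied so
denoising can be scored against the clean truth.

Lesion placement mimics the field symptomatology:

* nitrogen (N) — chlorotic wash starting from the inner/older leaves,
  grown outward from the rosette center;
* phosphorus (P) — dark purplish patches scattered over the canopy,
  grown around random seed points;
* potassium (K) — marginal scorch, grown inward from the leaf edges.

In every case the lesion is the requested number of plant pixels with the
lowest placement score, so the true fraction matches the request up to
one-pixel rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi

from .raster_core import hsv_to_rgb
from .diagnose import severity_for_ratio

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "LESION_COLORS",
    "generate_scene",
    "add_impulse_noise",
    "scene_battery",
]

# (hue, saturation, value) on the package's 0-255 planes
LESION_COLORS: dict[str, tuple[int, int, int]] = {
    "N": (40, 200, 175),  # yellow chlorosis
    "P": (200, 160, 115),  # dark purple
    "K": (14, 190, 130),  # brown scorch
}

BACKGROUND_RGB = (30, 28, 26)  # dark, near-achromatic growing bench


@dataclass(frozen=True)
class SceneSpec:
    """Parametric canopy scene; identical spec (incl. seed) ⇒ identical scene."""

    canvas: tuple[int, int] = (160, 160)  # (height, width) px
    leaf_count: int = 12
    base_hue: int = 85  # green on the 0-255 hue wheel
    base_sat: int = 170
    base_val: int = 150
    lesion_class: str = "none"  # one of N, P, K, none
    lesion_fraction: float = 0.0  # target fraction of plant area
    lesion_hue: int | None = None  # None -> class default
    noise_density: float = 0.02  # salt-and-pepper fraction of all pixels
    illum_gradient: float = 0.15  # peak-to-peak multiplicative brightness span
    seed: int = 0

    def __post_init__(self):
        if self.lesion_class not in ("N", "P", "K", "none"):
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")
        if not 0.0 <= self.lesion_fraction <= 0.6:
            raise ValueError(
                f"lesion_fraction must lie in [0, 0.6], got {self.lesion_fraction}"
            )
        if not 0.0 <= self.noise_density <= 0.2:
            raise ValueError(f"noise_density must lie in [0, 0.2], got {self.noise_density}")
        if self.canvas[0] < 32 or self.canvas[1] < 32:
            raise ValueError(f"canvas {self.canvas} too small for a rosette scene")


@dataclass(frozen=True)
class GroundTruth:
    plant_mask: np.ndarray
    lesion_mask: np.ndarray
    true_fraction: float
    nutrient: str  # N, P, K or healthy
    severity: str  # mild, moderate, severe or none


def _leaf_masks(spec: SceneSpec, rng: np.random.Generator) -> list[np.ndarray]:
    h, w = spec.canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    radius = min(h, w) / 2.0
    masks = []
    base_angles = np.linspace(0.0, 2.0 * np.pi, spec.leaf_count, endpoint=False)
    for phi0 in base_angles:
        phi = phi0 + rng.uniform(-0.3, 0.3)
        length = radius * rng.uniform(0.55, 0.8)
        halfwidth = length * rng.uniform(0.30, 0.45)
        ecy = cy + (length / 2.0) * np.sin(phi) + rng.uniform(-2, 2)
        ecx = cx + (length / 2.0) * np.cos(phi) + rng.uniform(-2, 2)
        dx, dy = xx - ecx, yy - ecy
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        masks.append((u / (length / 2.0)) ** 2 + (v / halfwidth) ** 2 <= 1.0)
    return masks


def _lesion_score(
    spec: SceneSpec,
    plant: np.ndarray,
    leaf_id: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lower score = corrupted earlier; class-dependent geometry."""
    h, w = spec.canvas
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if spec.lesion_class == "N":  # inner wash from the rosette center
        return np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    if spec.lesion_class == "K":
        # marginal scorch: finite-width bands (MARGIN_WIDTH px) along the
        # edges of individual leaves, leaf by leaf in random order; deeper
        # layers of a leaf are reached only after every affected leaf's
        # margin band is complete
        width = 4.0
        rank = rng.permutation(spec.leaf_count).astype(np.float64)
        score = np.full((h, w), np.inf)
        for i in range(spec.leaf_count):
            region = leaf_id == i
            if not region.any():
                continue
            edt = ndi.distance_transform_edt(region)
            layer = np.ceil(edt / width)
            s = layer * 1e6 + rank[i] * 1e3 + edt
            score[region] = s[region]
        return score
    # "P": patches around random seed pixels on the plant
    plant_idx = np.flatnonzero(plant)
    k = int(round(spec.lesion_fraction * plant_idx.size))
    n_seeds = max(2, int(round(k / 400.0)) + 1)
    chosen = rng.choice(plant_idx, size=min(n_seeds, plant_idx.size), replace=False)
    sy, sx = np.unravel_index(chosen, plant.shape)
    d = np.full(plant.shape, np.inf)
    for y0, x0 in zip(sy, sx):
        d = np.minimum(d, np.hypot(yy - y0, xx - x0))
    return d


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene and its ground truth.

    Returns the 8-bit RGB image (noise included if requested) and a
    :class:`GroundTruth` whose masks were captured before noise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas

    leaves = _leaf_masks(spec, rng)
    plant = np.zeros((h, w), dtype=bool)
    leaf_id = np.full((h, w), -1, dtype=np.int32)
    for i, m in enumerate(leaves):  # later leaves drawn on top
        plant |= m
        leaf_id[m] = i
    plant_area = int(plant.sum())

    # healthy tissue in HSV, with per-leaf hue/value variation + fine V texture
    hue_jit = rng.uniform(-6, 6, size=spec.leaf_count)
    val_jit = rng.uniform(-12, 12, size=spec.leaf_count)
    sat_jit = rng.uniform(-10, 10, size=spec.leaf_count)
    hsv = np.zeros((h, w, 3), dtype=np.float64)
    lid = np.where(leaf_id >= 0, leaf_id, 0)
    hsv[:, :, 0] = spec.base_hue + hue_jit[lid]
    hsv[:, :, 1] = spec.base_sat + sat_jit[lid]
    hsv[:, :, 2] = spec.base_val + val_jit[lid] + rng.normal(0.0, 4.0, size=(h, w))

    # lesion pixels: exactly k plant pixels with the lowest placement score
    lesion = np.zeros((h, w), dtype=bool)
    if spec.lesion_class != "none" and spec.lesion_fraction > 0 and plant_area > 0:
        k = int(round(spec.lesion_fraction * plant_area))
        score = _lesion_score(spec, plant, leaf_id, rng)
        score = np.where(plant, score, np.inf)
        order = np.argsort(score, axis=None, kind="stable")
        lesion.flat[order[:k]] = True
        lhue, lsat, lval = LESION_COLORS[spec.lesion_class]
        if spec.lesion_hue is not None:
            lhue = spec.lesion_hue
        hsv[:, :, 0][lesion] = lhue + rng.uniform(-3, 3, size=k)
        hsv[:, :, 1][lesion] = lsat + rng.uniform(-15, 15, size=k)
        hsv[:, :, 2][lesion] = lval + rng.uniform(-10, 10, size=k)

    hsv[:, :, 0] %= 256.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1], 0, 255)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2], 0, 255)
    rgb = hsv_to_rgb(hsv).astype(np.float64)

    bg = np.asarray(BACKGROUND_RGB, dtype=np.float64) + rng.uniform(-4, 4, size=(h, w, 3))
    rgb = np.where(plant[:, :, None], rgb, bg)

    # multiplicative illumination ramp across columns (hue-preserving)
    if spec.illum_gradient > 0:
        ramp = 1.0 + spec.illum_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        rgb *= ramp[None, :, None]
    img = np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)

    true_fraction = float(lesion.sum()) / plant_area if plant_area else 0.0
    if spec.lesion_class == "none" or true_fraction == 0.0:
        nutrient, severity = "healthy", "none"
    else:
        nutrient = spec.lesion_class
        severity = severity_for_ratio(true_fraction)
    truth = GroundTruth(
        plant_mask=plant,
        lesion_mask=lesion,
        true_fraction=true_fraction,
        nutrient=nutrient,
        severity=severity,
    )

    if spec.noise_density > 0:
        img = add_impulse_noise(img, spec.noise_density, seed=_noise_seed(spec.seed))
    return img, truth


def _noise_seed(seed: int) -> int:
    return (seed * 2654435761 + 97) % (2**31)


def add_impulse_noise(img: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Corrupt exactly round(density·W·H) pixels to pure black or white.

    Positions are drawn without replacement; black vs. white is a fair
    coin per pixel.  All three channels of a corrupted pixel are set.
    """
    if not 0.0 <= density <= 0.2:
        raise ValueError(f"density must lie in [0, 0.2], got {density}")
    img = np.asarray(img, dtype=np.uint8)
    out = img.copy()
    n = int(round(density * img.shape[0] * img.shape[1]))
    if n == 0:
        return out
    rng = np.random.default_rng(seed)
    pos = rng.choice(img.shape[0] * img.shape[1], size=n, replace=False)
    vals = rng.integers(0, 2, size=n).astype(np.uint8) * 255
    flat = out.reshape(-1, img.shape[2]) if img.ndim == 3 else out.reshape(-1, 1)
    flat[pos] = vals[:, None]
    return out


_BATTERY_COMBOS: tuple[tuple[str, float], ...] = (
    ("N", 0.05), ("N", 0.15), ("N", 0.35),
    ("P", 0.05), ("P", 0.15), ("P", 0.35),
    ("K", 0.05), ("K", 0.15), ("K", 0.35),
    ("none", 0.0),
)


def scene_battery(
    n: int, seed: int, base_spec: SceneSpec | None = None
) -> list[tuple[SceneSpec, np.ndarray, GroundTruth]]:
    """Balanced battery over {N, P, K}×{mild≈0.05, moderate≈0.15, severe≈0.35}
    plus healthy controls, cycled so class counts differ by at most one.

    Target fractions are jittered by ±0.01 per scene so the battery probes a
    neighborhood of each severity level rather than three exact fractions.
    """
    if n < 1:
        raise ValueError("battery size must be ≥ 1")
    base = base_spec or SceneSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)
    out = []
    for i in range(n):
        cls, frac = _BATTERY_COMBOS[i % len(_BATTERY_COMBOS)]
        jitter_rng = np.random.default_rng(int(child_seeds[2 * i]))
        if frac > 0:
            frac = frac + jitter_rng.uniform(-0.01, 0.01)
        spec = replace(
            base,
            lesion_class=cls,
            lesion_fraction=float(frac),
            seed=int(child_seeds[2 * i + 1]),
        )
        img, truth = generate_scene(spec)
        out.append((spec, img, truth))
    return out
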