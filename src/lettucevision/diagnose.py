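"""Deficient-tissue quantification and rule-based N/P/K classification.

The severity proxy is the deficient-tissue ratio: the fraction of plant
canopy pixels labeled deficient by the segmentation.  The nutrient is
identified from the hue histogram of the deficient region — the
characteristic discolorations differ in hue (nitrogen: yellowing;
phosphorus: dark purple; potassium: marginal browning) — by checking
which configured hue band contains the predominant (modal) hue.

No model is trained: classification applies a fixed, configurable rule
table, and every fired rule is recorded in the report's trace.  The
default ratio cutpoints (0.02 / 0.10 / 0.25 for healthy|mild|moderate|
severe) and hue bands are calibration defaults of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import HUE_BAND_PRESETS

__all__ = [
    "ClassificationRules",
    "ColorHistogramFeature",
    "DeficiencyReport",
    "deficient_ratio",
    "plant_mask_from_hsv",
    "color_features",
    "severity_for_ratio",
    "classify",
]

DEFAULT_CUTPOINTS = (0.02, 0.10, 0.25)  # healthy|mild, mild|moderate, moderate|severe


@dataclass(frozen=True)
class ClassificationRules:
    """Rule table: nutrient hue bands and severity ratio cutpoints."""

    bands: dict = field(
        default_factory=lambda: {
            "N": HUE_BAND_PRESETS["nband"],
            "P": HUE_BAND_PRESETS["pband"],
            "K": HUE_BAND_PRESETS["kband"],
        }
    )
    cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS

    def __post_init__(self):
        a, b, c = self.cutpoints
        if not 0 < a < b < c:
            raise ValueError(f"cutpoints must be increasing and positive, got {self.cutpoints}")
        for name, (lo, hi) in self.bands.items():
            if lo > hi:
                raise ValueError(f"inverted hue band for {name}: [{lo}, {hi}]")


@dataclass(frozen=True)
class ColorHistogramFeature:
    """Hue histogram of the deficient region with its predominant level."""

    hue_counts: np.ndarray  # 256 bins
    n_pixels: int
    mode_hue: int  # lowest level on ties; 0 when empty
    mode_frequency: float  # fraction of masked pixels at the modal hue
    band_fractions: dict  # per configured band, fraction of masked pixels


@dataclass(frozen=True)
class DeficiencyReport:
    ratio: float
    nutrient: str  # one of N, P, K, healthy
    severity: str  # one of mild, moderate, severe, none
    trace: tuple = ()

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "nutrient": self.nutrient,
            "severity": self.severity,
            "trace": list(self.trace),
        }


def deficient_ratio(mask: np.ndarray, plant_mask: np.ndarray) -> float:
    """|deficient ∧ plant| / |plant|; the plant mask must be nonempty."""
    mask = np.asarray(mask, dtype=bool)
    plant = np.asarray(plant_mask, dtype=bool)
    if mask.shape != plant.shape:
        raise ValueError(f"mask shapes differ: {mask.shape} vs {plant.shape}")
    denom = int(plant.sum())
    if denom == 0:
        raise ValueError("empty plant mask: the deficient-tissue ratio is undefined")
    return int((mask & plant).sum()) / denom


def plant_mask_from_hsv(
    hsv: np.ndarray, sat_min: float = 50.0, val_min: float = 40.0
) -> np.ndarray:
    """Plant canopy vs. dark background: chromatic (S) and bright enough (V).

    Covers both healthy green tissue and lesion colors, which all carry
    saturation the dark background lacks.  Meant for the *denoised*,
    pre-enhancement HSV image (enhancement redistributes V levels).
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    return (hsv[:, :, 1] >= sat_min) & (hsv[:, :, 2] >= val_min)


def color_features(
    hsv: np.ndarray, mask: np.ndarray, rules: ClassificationRules | None = None
) -> ColorHistogramFeature:
    """Hue histogram over masked pixels; modal hue (lowest level on ties)."""
    rules = rules or ClassificationRules()
    hsv = np.asarray(hsv, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    hues = np.clip(np.floor(hsv[:, :, 0][mask] + 0.5), 0, 255).astype(np.intp)
    counts = np.bincount(hues, minlength=256)
    n = int(counts.sum())
    if n == 0:
        return ColorHistogramFeature(
            hue_counts=counts, n_pixels=0, mode_hue=0, mode_frequency=0.0,
            band_fractions={k: 0.0 for k in rules.bands},
        )
    mode = int(np.argmax(counts))  # argmax takes the lowest level on ties
    fractions = {
        name: float(counts[int(np.ceil(lo)) : int(np.floor(hi)) + 1].sum()) / n
        for name, (lo, hi) in rules.bands.items()
    }
    return ColorHistogramFeature(
        hue_counts=counts,
        n_pixels=n,
        mode_hue=mode,
        mode_frequency=float(counts[mode]) / n,
        band_fractions=fractions,
    )


def severity_for_ratio(ratio: float, cutpoints=DEFAULT_CUTPOINTS) -> str:
    a, b, c = cutpoints
    if ratio < a:
        return "none"
    if ratio < b:
        return "mild"
    if ratio < c:
        return "moderate"
    return "severe"


def classify(
    features: ColorHistogramFeature,
    ratio: float,
    rules: ClassificationRules | None = None,
) -> DeficiencyReport:
    """Apply the rule table; deterministic, with a trace of fired rules.

    Severity comes from the ratio cutpoints; the nutrient from the hue
    band containing the modal hue of the deficient region (falling back
    to the band holding the largest pixel fraction).  Below the healthy
    cutpoint, or when no band matches at all, the report is (healthy,
    none).
    """
    rules = rules or ClassificationRules()
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    trace = []
    severity = severity_for_ratio(ratio, rules.cutpoints)
    trace.append(f"ratio={ratio:.4f} -> severity '{severity}'")
    if severity == "none" or features.n_pixels == 0:
        trace.append("below healthy cutpoint or empty region -> healthy")
        return DeficiencyReport(ratio=ratio, nutrient="healthy", severity="none",
                                trace=tuple(trace))
    nutrient = None
    for name, (lo, hi) in rules.bands.items():
        if lo <= features.mode_hue <= hi:
            nutrient = name
            trace.append(f"mode hue {features.mode_hue} in {name} band [{lo}, {hi}]")
            break
    if nutrient is None:
        best = max(features.band_fractions, key=lambda k: features.band_fractions[k])
        if features.band_fractions[best] > 0:
            nutrient = best
            trace.append(
                f"mode hue {features.mode_hue} outside all bands; "
                f"largest band fraction {best} ({features.band_fractions[best]:.3f})"
            )
        else:
            trace.append("no band contains any deficient pixels -> healthy")
            return DeficiencyReport(ratio=ratio, nutrient="healthy", severity="none",
                                    trace=tuple(trace))
    return DeficiencyReport(ratio=ratio, nutrient=nutrient, severity=severity,
                            trace=tuple(trace))
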