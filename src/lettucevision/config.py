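"""Pipeline configuration: namespaced tunables with strict key checking.

Every tunable of the processing stages lives here under the namespaces
``denoise.*``, ``enhance.*``, ``edges.*``, ``segment.*``, ``diagnose.*``,
``io.*`` and ``logging.*``.  Unknown keys are rejected (a typo'd parameter
must never be silently ignored); missing keys take the documented
defaults.  The fully resolved configuration is echoed into every run's
output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .denoise import DEFAULT_THETA
from .enhance import ClaheParams, FusionParams
from .segment import HUE_BAND_PRESETS, HsvBands, SegmentParams
from .diagnose import DEFAULT_CUTPOINTS, ClassificationRules

__all__ = ["ConfigError", "PipelineConfig", "load_config", "dump_config"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigError(f"unknown config key(s) under '{path}': {', '.join(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values under '{path}': {exc}") from exc


@dataclass(frozen=True)
class DenoiseConfig:
    theta: float = DEFAULT_THETA  # variance threshold selecting the 3×3 window


@dataclass(frozen=True)
class EnhanceConfig:
    method: str = "clgce"  # one of ghe, clahe, clgce
    tile_grid: tuple[int, int] = (8, 8)
    base: float = 4.0
    scale: float = 0.1
    threshold: float = 128.0
    alpha_smooth: float = 0.05
    invert_weights: bool = True
    k: float = 0.05
    m: float = 0.05
    l0: float = 128.0
    sigma0: float = 50.0

    def __post_init__(self):
        if self.method not in ("ghe", "clahe", "clgce"):
            raise ValueError(f"enhance method must be ghe|clahe|clgce, got {self.method!r}")

    def clahe_params(self) -> ClaheParams:
        return ClaheParams(
            tile_grid=tuple(self.tile_grid),
            base=self.base,
            scale=self.scale,
            threshold=self.threshold,
            alpha_smooth=self.alpha_smooth,
            invert_weights=self.invert_weights,
        )

    def fusion_params(self) -> FusionParams:
        return FusionParams(
            k=self.k, m=self.m, l0=self.l0, sigma0=self.sigma0, clahe=self.clahe_params()
        )


@dataclass(frozen=True)
class EdgesConfig:
    ratio: float = 0.4  # T_low / T_high
    sigma_blur: float = 1.0  # Gaussian pre-smoothing; ≤ 0 disables


@dataclass(frozen=True)
class SegmentConfig:
    block_size: int = 16
    dilate_radius: int = 5
    close_radius: int = 3
    bands: tuple[str, ...] = ("nband", "pband", "kband")
    sat_range: tuple[float, float] = (60.0, 255.0)
    val_range: tuple[float, float] = (40.0, 255.0)

    def hsv_bands(self) -> list[HsvBands]:
        out = []
        for name in self.bands:
            if name not in HUE_BAND_PRESETS:
                raise ConfigError(
                    f"unknown band preset {name!r}; available: {sorted(HUE_BAND_PRESETS)}"
                )
            out.append(
                HsvBands(
                    hue=HUE_BAND_PRESETS[name],
                    sat=tuple(self.sat_range),
                    val=tuple(self.val_range),
                )
            )
        return out

    def params(self, edges_cfg: EdgesConfig) -> SegmentParams:
        return SegmentParams(
            block_size=self.block_size,
            dilate_radius=self.dilate_radius,
            close_radius=self.close_radius,
            canny_ratio=edges_cfg.ratio,
            canny_sigma=edges_cfg.sigma_blur,
        )


@dataclass(frozen=True)
class DiagnoseConfig:
    cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS
    plant_sat_min: float = 50.0
    plant_val_min: float = 40.0

    def rules(self) -> ClassificationRules:
        return ClassificationRules(cutpoints=tuple(self.cutpoints))


@dataclass(frozen=True)
class IoConfig:
    save_intermediates: bool = False


@dataclass(frozen=True)
class LoggingConfig:
    level: str = "INFO"


_SECTIONS = {
    "denoise": DenoiseConfig,
    "enhance": EnhanceConfig,
    "edges": EdgesConfig,
    "segment": SegmentConfig,
    "diagnose": DiagnoseConfig,
    "io": IoConfig,
    "logging": LoggingConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    edges: EdgesConfig = field(default_factory=EdgesConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    diagnose: DiagnoseConfig = field(default_factory=DiagnoseConfig)
    io: IoConfig = field(default_factory=IoConfig)
    logging: LoggingConfig = field(default_factory=LoggingConfig)

    @classmethod
    def from_dict(cls, data: dict | None) -> "PipelineConfig":
        data = data or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        unknown = sorted(set(data) - set(_SECTIONS))
        if unknown:
            raise ConfigError(f"unknown config section(s): {', '.join(unknown)}")
        kwargs = {
            name: _from_dict(section_cls, data.get(name) or {}, name)
            for name, section_cls in _SECTIONS.items()
        }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        return plain(self)


def load_config(path: str | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the documented defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
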