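"""Declarative pipeline configuration.

One YAML mapping holds the calibration profile, the HSL threshold bands
and the component-size thresholds.  Defaults reproduce the reference
instrument (14 µm pitch, ×15.71, 1280×3000 frames) with the desktop-scanner
band values; any key may be overridden in the file or by CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationProfile
from .errors import ConfigError
from .segmentation import Band, BandSet

__all__ = ["PipelineConfig", "load_config", "default_config", "config_to_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    calibration: CalibrationProfile = field(default_factory=CalibrationProfile)
    bands: BandSet = field(default_factory=BandSet)
    #: components smaller than this are impurities (px; ≈2.4 mm² at default scale)
    min_impurity_px: int = 50
    #: components smaller than this are not leaves (px; ≈9.7 mm²)
    min_leaf_px: int = 200
    background_rgb: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.min_impurity_px < 1 or self.min_leaf_px < 1:
            raise ConfigError("size thresholds must be >= 1 pixel")


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _band_from_mapping(name: str, raw: dict) -> Band:
    try:
        return Band(
            name=name,
            h_min=int(raw["h"][0]), h_max=int(raw["h"][1]),
            s_min=int(raw["s"][0]), s_max=int(raw["s"][1]),
            l_min=int(raw["l"][0]), l_max=int(raw["l"][1]),
        )
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid band {name!r}: {exc}") from exc


_BAND_KEYS = {"green": "green", "yellow": "yellow",
              "green2": "green-2", "green3": "green-3", "green4": "green-4"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a configuration file, overriding defaults key by key."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")

    base = default_config()
    cal_raw = raw.get("calibration", {})
    try:
        calibration = CalibrationProfile(
            pixel_pitch_um=float(cal_raw.get("pixel_pitch_um", base.calibration.pixel_pitch_um)),
            magnification=float(cal_raw.get("magnification", base.calibration.magnification)),
            channel_offset_green=int(cal_raw.get("channel_offset_green", base.calibration.channel_offset_green)),
            channel_offset_blue=int(cal_raw.get("channel_offset_blue", base.calibration.channel_offset_blue)),
            frame_height_px=int(cal_raw.get("frame_height_px", base.calibration.frame_height_px)),
            frame_width_px=int(cal_raw.get("frame_width_px", base.calibration.frame_width_px)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid calibration: {exc}") from exc

    bands_raw = raw.get("bands", {})
    band_kwargs = {}
    for key, band_name in _BAND_KEYS.items():
        if key in bands_raw:
            band_kwargs[key] = _band_from_mapping(band_name, bands_raw[key])
    try:
        bands = BandSet(**{k: v for k, v in band_kwargs.items()}) if band_kwargs else base.bands
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    try:
        return PipelineConfig(
            calibration=calibration,
            bands=bands,
            min_impurity_px=int(raw.get("min_impurity_px", base.min_impurity_px)),
            min_leaf_px=int(raw.get("min_leaf_px", base.min_leaf_px)),
            background_rgb=tuple(raw.get("background_rgb", base.background_rgb)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc


def config_to_dict(config: PipelineConfig) -> dict:
    """Serialisable view of a configuration (used by ``config --show``)."""
    cal = config.calibration

    def band(b: Band) -> dict:
        return {"h": [b.h_min, b.h_max], "s": [b.s_min, b.s_max], "l": [b.l_min, b.l_max]}

    return {
        "calibration": {
            "pixel_pitch_um": cal.pixel_pitch_um,
            "magnification": cal.magnification,
            "mm_per_pixel": cal.mm_per_pixel,
            "area_per_pixel_mm2": cal.area_per_pixel_mm2,
            "channel_offset_green": cal.channel_offset_green,
            "channel_offset_blue": cal.channel_offset_blue,
            "frame_height_px": cal.frame_height_px,
            "frame_width_px": cal.frame_width_px,
        },
        "bands": {
            "green": band(config.bands.green),
            "yellow": band(config.bands.yellow),
            "green2": band(config.bands.green2),
            "green3": band(config.bands.green3),
            "green4": band(config.bands.green4),
        },
        "min_impurity_px": config.min_impurity_px,
        "min_leaf_px": config.min_leaf_px,
        "background_rgb": list(config.background_rgb),
    }
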