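"""Run configuration: typed, defaulted, and strictly validated.

One YAML file drives the whole pipeline.  Every parameter has the
field-standard default (300-px size filter, 7-px movement threshold, 4-h
quiescence rule, 2-observation movement confirmation, 10-h occupancy
window), unknown keys are hard errors (no silently ignored typos), and a
parsed config round-trips through serialization unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class PathsConfig:
    stack: str = ""
    sidecar: str = ""
    manifest: str = ""  # synthetic-run manifest; supplies grid + times
    out_dir: str = "out"


@dataclass
class AlignmentConfig:
    reference_points: str = ""  # CSV: src_row, src_col, dst_row, dst_col
    allow_scale: bool = False


@dataclass
class GridConfig:
    bounds: list = field(default_factory=list)  # [r0, c0, r1, c1]; empty = full frame
    rows: int = 25
    cols: int = 2
    excluded: list = field(default_factory=list)
    time_exclusions: str = ""  # CSV: arena_index, t_start_h, t_end_h
    auto_qc_sd: float = 5.0


@dataclass
class DetectionConfig:
    min_area: int = 300
    method: str = "otsu"
    polarity: str = "dark_objects"
    threshold: float | None = None
    min_contrast: float = 20.0


@dataclass
class VitalityConfig:
    move_threshold: float = 7.0
    quiescent_h: float = 4.0
    confirm_m: int = 2
    occupancy_window_h: float = 10.0
    compensate_shifts: bool = True
    agree_frac: float = 0.5
    min_shift: float = 3.0


@dataclass
class SurvivalConfig:
    group: str = "run"
    lethality_at: list = field(default_factory=list)
    include_multi: bool = True


@dataclass
class SimulateConfig:
    """Pass-through section for the simulate subcommand; keys mirror the
    synthetic generator's parameters."""

    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    vitality: VitalityConfig = field(default_factory=VitalityConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    simulate: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "paths": PathsConfig,
    "alignment": AlignmentConfig,
    "grid": GridConfig,
    "detection": DetectionConfig,
    "vitality": VitalityConfig,
    "survival": SurvivalConfig,
}


def _build_section(name: str, cls, raw: dict, errors: list[str]):
    obj = cls()
    for key, value in raw.items():
        if not hasattr(obj, key):
            errors.append(f"unknown key {name}.{key}")
            continue
        setattr(obj, key, value)
    return obj


def _check_ranges(cfg: RunConfig, errors: list[str]) -> None:
    det, vit, grd = cfg.detection, cfg.vitality, cfg.grid
    if det.min_area < 1:
        errors.append("detection.min_area must be >= 1")
    if det.method not in ("otsu", "fixed"):
        errors.append(f"detection.method must be otsu or fixed, got {det.method!r}")
    if det.method == "fixed" and det.threshold is None:
        errors.append("detection.method fixed requires detection.threshold")
    if det.polarity not in ("dark_objects", "light_objects"):
        errors.append(f"detection.polarity invalid: {det.polarity!r}")
    if det.min_contrast < 0:
        errors.append("detection.min_contrast must be >= 0")
    if vit.move_threshold < 0:
        errors.append("vitality.move_threshold must be >= 0")
    if vit.quiescent_h <= 0:
        errors.append("vitality.quiescent_h must be > 0")
    if vit.confirm_m < 1:
        errors.append("vitality.confirm_m must be >= 1")
    if vit.occupancy_window_h <= 0:
        errors.append("vitality.occupancy_window_h must be > 0")
    if not 0 < vit.agree_frac < 1:
        errors.append("vitality.agree_frac must be in (0, 1)")
    if vit.min_shift < 0:
        errors.append("vitality.min_shift must be >= 0")
    if grd.rows < 1 or grd.cols < 1:
        errors.append("grid.rows and grid.cols must be >= 1")
    if grd.bounds and len(grd.bounds) != 4:
        errors.append("grid.bounds must be [r0, c0, r1, c1]")


def validate_config(raw: dict | str) -> RunConfig:
    """Parse and validate a raw config (YAML text or a mapping).

    Returns a fully defaulted :class:`RunConfig`; raises :class:`ConfigError`
    listing every unknown key, missing requirement and out-of-range value.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    errors: list[str] = []
    cfg = RunConfig()
    for key, value in raw.items():
        if key == "seed":
            if not isinstance(value, int):
                errors.append("seed must be an integer")
            else:
                cfg.seed = value
        elif key == "simulate":
            if not isinstance(value, dict):
                errors.append("simulate section must be a mapping")
            else:
                cfg.simulate = value
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(f"section {key} must be a mapping")
            else:
                setattr(cfg, key, _build_section(key, _SECTIONS[key], value, errors))
        else:
            errors.append(f"unknown key {key}")
    _check_ranges(cfg, errors)
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    return validate_config(Path(path).read_text())
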