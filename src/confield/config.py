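"""Pipeline configuration: nested defaults, YAML loading, strict keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cf import DEFAULT_SIGMA_GRID_MM
from .synthetic import SyntheticConfig

SCHEMA_VERSION = 1


@dataclass
class PreprocessConfig:
    window_period_s: float = 210.0
    polyorder: int = 3


@dataclass
class PRFConfig:
    """Grid ranges and optimizer settings for the pRF stage.

    Grids span the stimulated field; bounds allow refinement slightly
    beyond it. ``hrf`` toggles canonical hemodynamic convolution of the
    overlap series; it is off by default because the bundled generator
    produces neural-level signals, and should be enabled for BOLD data.
    """

    n_ecc: int = 8
    n_angle: int = 12
    sigma_grid: tuple = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0)
    hrf: bool = False
    iterative: bool = False  # grid fit only by default; refinement is opt-in
    r2_threshold: float = 0.2

    def xy_grids(self, field_radius: float):
        """Polar grid of candidate centers covering the aperture."""
        import numpy as np

        ecc = np.linspace(field_radius / self.n_ecc, field_radius, self.n_ecc)
        ang = np.linspace(0, 2 * np.pi, self.n_angle, endpoint=False)
        x = np.unique(np.round(np.outer(ecc, np.cos(ang)).ravel(), 6))
        y = np.unique(np.round(np.outer(ecc, np.sin(ang)).ravel(), 6))
        return x, y


@dataclass
class CFConfig:
    sigma_grid_mm: tuple = DEFAULT_SIGMA_GRID_MM
    n_folds: int = 4
    ratio_floor: float = 0.01


@dataclass
class PipelineConfig:
    """Fully resolved settings for one end-to-end run."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    conditions: tuple = ("rest", "movie")
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    prf: PRFConfig = field(default_factory=PRFConfig)
    cf: CFConfig = field(default_factory=CFConfig)

    def __post_init__(self):
        self.synthetic.seed = self.seed


_SECTIONS = {
    "synthetic": SyntheticConfig,
    "preprocess": PreprocessConfig,
    "prf": PRFConfig,
    "cf": CFConfig,
}


def _build(cls, payload: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in payload:
            v = payload[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def config_from_dict(payload: dict) -> PipelineConfig:
    """Build a PipelineConfig from nested dicts; unknown keys are rejected."""
    payload = dict(payload)
    version = payload.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    kwargs = {"schema_version": version}
    for key, cls in _SECTIONS.items():
        if key in payload:
            kwargs[key] = _build(cls, payload.pop(key) or {}, key)
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - top_names
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for k, v in payload.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(payload)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg: PipelineConfig, path) -> Path:
    """Write the fully resolved configuration next to the outputs."""
    path = Path(path)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    path.write_text(yaml.safe_dump(clean(config_to_dict(cfg)), sort_keys=False))
    return path


def apply_overrides(cfg_dict: dict, overrides: list[str]) -> dict:
    """Apply ``key.subkey=value`` overrides to a nested config dict."""
    for ov in overrides:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} is not of the form key=value")
        key, value = ov.split("=", 1)
        parts = key.split(".")
        node = cfg_dict
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(value)
    return cfg_dict
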