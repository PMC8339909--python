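"""Structured run configuration: one JSON document drives a whole pipeline.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults); missing keys take the documented defaults, which are logged
when a config is loaded.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError

from .cable import SimulatorConfig

logger = logging.getLogger("rcemu")

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulatorSettings(_Strict):
    length_mm: float = 24.0
    dx_mm: float = 0.3
    dt_ms: float = 0.1
    substeps: int = 10
    stim_nodes: int = 3
    stim_amplitude: float = 1.0
    stim_duration_ms: float = 2.0
    threshold_act: float = 0.7
    threshold_rep: float = 0.1
    prepace_beats: int = 8
    snapshot_offset_ms: float = 20.0
    erp_bracket: tuple[int, int] = (100, 2000)

    def to_simulator_config(self) -> SimulatorConfig:
        return SimulatorConfig(**self.model_dump())


class DesignSettings(_Strict):
    n_points: int = 500
    n_candidate_designs: int = 200


class ProtocolSettings(_Strict):
    s2_resolution: float = 10.0
    s2_range: tuple[float, float] = (170.0, 360.0)
    cv_noise_sd: float = 0.05
    apd_noise_sd: float = 5.0
    erp_s1_list: tuple[float, ...] = (600.0, 500.0, 400.0)
    include_s1_equals_s2: bool = True


class EmulatorSettings(_Strict):
    n_components_s2: int = 3
    n_components_erp: int = 2
    grid_start: float = 160.0
    grid_stop: float = 600.0
    grid_step: float = 1.0
    gp_n_starts: int = 8


class CalibrationSettings(_Strict):
    erp_mixture_terms: int = 10
    map_starts: int = 16
    n_walkers: int = 32
    n_steps: int = 2000
    burn: int = 1000
    thin: int = 5
    sample_noise: bool = False


class RunConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    outdir: str = "."
    simulator: SimulatorSettings = SimulatorSettings()
    design: DesignSettings = DesignSettings()
    protocol: ProtocolSettings = ProtocolSettings()
    emulator: EmulatorSettings = EmulatorSettings()
    calibration: CalibrationSettings = CalibrationSettings()


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    """Load and validate a JSON config; defaults filled and logged."""
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as err:
            raise ConfigError(f"{path}: not valid JSON: {err}") from err
    try:
        cfg = RunConfig(**raw)
    except ValidationError as err:
        first = err.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"{path}: invalid config at key '{key}': {first['msg']}") from err
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigError(f"{path}: schema_version {cfg.schema_version} != {SCHEMA_VERSION}")
    defaults = RunConfig()
    for name in ("seed", "outdir"):
        if name not in raw:
            logger.info("config %s: using default %s=%r", path, name, getattr(defaults, name))
    for section in ("simulator", "design", "protocol", "emulator", "calibration"):
        sub = raw.get(section, {})
        model = getattr(cfg, section)
        for fname in type(model).model_fields:
            if fname not in sub:
                logger.info("config %s: using default %s.%s=%r", path, section,
                            fname, getattr(model, fname))
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.model_dump(), fh, indent=2)
        fh.write("\n")
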