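"""Run configuration: YAML-backed, validated, with named defaults per stage.

Unknown keys are rejected by name so typos (``psf_sgima``) fail loudly.  A
run is driven either by a simulation block (synthetic data) or by input
paths (movie TIFFs + mask + optional landmarks) — exactly one of the two.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .simulate import SimulationConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration failed validation; message lists every failure."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationBlock(_Block):
    mother_radius: float = Field(2.0, gt=0)
    bud_radius: float = Field(1.0, ge=0)
    center_spacing: Optional[float] = None
    pixel_size: float = Field(0.1, gt=0)
    frame_interval: float = Field(1.0, gt=0)
    n_frames: int = Field(180, ge=1)
    event_rate_daughter: float = Field(0.004, ge=0)
    event_rate_mother: float = Field(0.002, ge=0)
    lifetime_mean: Union[float, dict] = 30.0
    lifetime_cv: Union[float, dict] = 0.3
    punctum_amplitude: float = Field(120.0, ge=0)
    diffuse_density: float = Field(30.0, ge=0)
    diffuse_polarization: float = Field(1.0, ge=0)
    diffuse_profile: Literal["flat", "tip"] = "flat"
    cytoplasm_density: float = Field(0.0, ge=0)
    internalization_depth: float = Field(0.2, ge=0)
    psf_sigma: float = Field(0.077, gt=0)
    camera_offset: float = Field(100.0, ge=0)
    read_noise_sd: float = Field(5.0, ge=0)
    shot_noise: bool = True
    n_channels: Literal[1, 2] = 1
    channel2_fraction: float = Field(0.5, ge=0, le=1)
    channel2_offset: float = 1.0
    margin: float = Field(0.8, gt=0)

    def to_simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.model_dump())


class InputBlock(_Block):
    movie_paths: list[str]
    mask_path: Optional[str] = None  # None: Otsu fallback on the median projection
    landmarks_path: Optional[str] = None
    pixel_size: float = Field(..., gt=0)
    frame_interval: float = Field(..., gt=0)


class KymoParams(_Block):
    band_halfwidth: float = Field(0.25, gt=0)
    reducer: Literal["max", "mean"] = "max"
    montage_stride: int = Field(1, ge=1)


class EventParams(_Block):
    k_threshold: float = Field(5.0, gt=0)
    psf_sigma: float = Field(0.077, gt=0)
    max_disp: float = Field(0.4, gt=0)
    max_gap: int = Field(1, ge=0)
    min_frames: int = Field(3, ge=1)
    censor_policy: Literal["exclude", "keep"] = "exclude"


class ProfileParams(_Block):
    band_halfwidth: float = Field(0.25, gt=0)
    background: Literal["interior_median", "constant", "none"] = "interior_median"


class RunConfig(_Block):
    simulation: Optional[SimulationBlock] = None
    inputs: Optional[InputBlock] = None
    kymo: KymoParams = KymoParams()
    events: EventParams = EventParams()
    profiles: ProfileParams = ProfileParams()
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' or 'inputs' must be given")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigError` listing every problem, naming unknown keys.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"]) or "<root>"
            lines.append(f"  {loc}: {e['msg']}")
        raise ConfigError(f"{path}: invalid configuration:\n" + "\n".join(lines)) from err


def save_config(config: RunConfig, path: str | Path) -> None:
    """Echo a configuration back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
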