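"""Run configuration: one YAML file drives the whole pipeline.

The file has four sections — ``geometry``, ``schedule``, ``simulation``
and ``analysis`` — validated strictly on load (unknown keys are
rejected).  All randomness flows from the single mandatory
``simulation.seed``; module-level sub-streams are derived from it, so a
config plus the package version pins every output bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import BaseplateGeometry
from .schedule import LightSchedule

__all__ = ["SimulationConfig", "AnalysisConfig", "RunConfig", "load_config",
           "default_config_yaml"]


def _from_mapping(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section}' section: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class SimulationConfig:
    """Synthetic-cage parameters (see :mod:`cagetrack.simulate`)."""

    seed: int
    strain: str = "high"
    n_animals: int = 3
    duration_h: float = 24.0
    gt_rate_hz: float = 25.0
    scan_rate_hz: float = 3.0
    p_read: float = 0.9

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation.seed is mandatory for reproducibility")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage parameters."""

    grid_step_s: float = 1.0
    bin_min: float = 6.0
    smoothing_bins: int = 5
    correction_factor: float = 1.4
    apply_correction: bool = False
    huddle_radius_mm: float = 50.0
    anticipation_window: tuple[str, str] = ("18:00", "19:00")
    exclude_before_first_dark: bool = False
    stop_at_lights_on: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "anticipation_window", tuple(self.anticipation_window)
        )

    @property
    def bin_width_s(self) -> float:
        return self.bin_min * 60.0


@dataclass(frozen=True)
class RunConfig:
    geometry: BaseplateGeometry = field(default_factory=BaseplateGeometry)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    simulation: SimulationConfig | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {"geometry", "schedule", "simulation", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown top-level section(s): {sorted(unknown)}")
    geometry = _from_mapping(BaseplateGeometry, raw.get("geometry", {}), "geometry")
    schedule = _from_mapping(LightSchedule, raw.get("schedule", {}), "schedule")
    simulation = None
    if "simulation" in raw:
        simulation = _from_mapping(SimulationConfig, raw["simulation"], "simulation")
    analysis = _from_mapping(AnalysisConfig, raw.get("analysis", {}), "analysis")
    return RunConfig(
        geometry=geometry, schedule=schedule, simulation=simulation, analysis=analysis
    )


def default_config_yaml(seed: int = 1) -> str:
    """A complete, commented default configuration."""
    return f"""\
# cagetrack run configuration
geometry:
  n_cols: 3
  n_rows: 6
  pitch_mm: 50.0
schedule:
  lights_on: "07:00"
  lights_off: "19:00"
  start_clock: "12:00"   # cage transferred onto the rig at noon
simulation:
  seed: {seed}            # mandatory; every random stream derives from it
  strain: high           # high | low | intermediate, see STRAIN_PRESETS
  n_animals: 3
  duration_h: 24.0
  gt_rate_hz: 25.0
  scan_rate_hz: 3.0
  p_read: 0.9
analysis:
  grid_step_s: 1.0
  bin_min: 6.0
  smoothing_bins: 5
  correction_factor: 1.4
  apply_correction: false   # the 1.4x rescale is opt-in, never silent
  huddle_radius_mm: 50.0
  anticipation_window: ["18:00", "19:00"]
  exclude_before_first_dark: false
  stop_at_lights_on: null
"""
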