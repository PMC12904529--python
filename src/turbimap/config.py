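"""Validated YAML run configuration for the command-line pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .calibration import PAPER_CALIBRATION, CalibrationModel
from .errors import ValidationError
from .geometry import VesselGeometry
from .scattering import acquisition_schedule, scan_plan
from .synthetic import (
    DEFAULT_AMPLITUDE,
    DEFAULT_EXPOSURES,
    CameraModel,
    GrowthScenario,
    antibiotic_scenario,
    banded_scenario,
    fermentation_scenario,
)


class GeometryConfig(BaseModel):
    radius_mm: float = 65.0
    scan_window_height_mm: float = 140.0
    liquid_top_mm: float = 8.0
    camera_pixel_pitch_mm: float = 0.5
    dark_attenuation: float = 0.05

    def build(self) -> VesselGeometry:
        return VesselGeometry(**self.model_dump())


class CameraConfig(BaseModel):
    gain: float = 2.0
    read_noise_sd: float = 3.0
    black_level: float = 100.0
    full_well: float = 65535.0
    exposures: list[float] = Field(default_factory=lambda: list(DEFAULT_EXPOSURES))

    def build(self) -> CameraModel:
        return CameraModel(
            gain=self.gain,
            read_noise_sd=self.read_noise_sd,
            black_level=self.black_level,
            full_well=self.full_well,
        )


class ScanConfig(BaseModel):
    spacing_mm: float = 5.0
    span_mm: float = 125.0
    start_mm: float = 10.0


class ScheduleConfig(BaseModel):
    interval_min: float = 10.0
    duration_h: float = 23.0
    n_timepoints: int | None = None  # override for scaled-down runs


class ScenarioConfig(BaseModel):
    kind: Literal["fermentation", "banded", "antibiotic"] = "fermentation"
    rho0: float | None = None
    fold: float = 2.0
    folds: tuple[float, float, float] = (2.5, 1.5, 2.5)
    band_edges_mm: tuple[float, float] = (45.0, 80.0)


class FitConfig(BaseModel):
    window: tuple[float, float] = (5.0, 30.0)
    row_halfwidth: int = 2

    @field_validator("window")
    @classmethod
    def _ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError("fit window must be (min, max) with min < max")
        return v


class RunConfig(BaseModel):
    """Everything a `turbimap simulate` run needs, with defaults
    mirroring the reference instrument settings (5 mm laser spacing over
    125 mm, 5-30 mm fit window, 10-minute intervals over 23 h, drop the
    2 lowest calibration points, mask the 55 and 70 mm rows)."""

    seed: int = 1
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    camera: CameraConfig = Field(default_factory=CameraConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    calibration: str = "paper-default"  # or a path to a model JSON
    exclude_lowest: int = 2
    mask_heights: list[float] = Field(default_factory=lambda: [55.0, 70.0])
    amplitude: float = DEFAULT_AMPLITUDE

    @model_validator(mode="after")
    def _check_files(self):
        if self.calibration != "paper-default" and not Path(self.calibration).exists():
            raise ValueError(f"calibration file not found: {self.calibration}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(raw)
        except Exception as exc:  # surfaced as a validation failure (exit 2)
            raise ValidationError(f"invalid run config {path}: {exc}") from exc

    def load_calibration(self) -> CalibrationModel:
        if self.calibration == "paper-default":
            return PAPER_CALIBRATION
        from .io import read_calibration

        return read_calibration(self.calibration)

    def timepoints(self):
        if self.schedule.n_timepoints is not None:
            import numpy as np

            return tuple(
                np.linspace(0.0, self.schedule.duration_h, self.schedule.n_timepoints)
            )
        return tuple(acquisition_schedule(self.schedule.interval_min, self.schedule.duration_h))

    def build_scenario(self) -> GrowthScenario:
        geometry = self.geometry.build()
        heights = tuple(
            scan_plan(self.scan.spacing_mm, self.scan.span_mm, self.scan.start_mm)
        )
        common = dict(
            timepoints_h=self.timepoints(),
            laser_heights_mm=heights,
            geometry=geometry,
            rng_seed=self.seed,
        )
        if self.scenario.rho0 is not None:
            common["rho0"] = self.scenario.rho0
        kind = self.scenario.kind
        if kind == "fermentation":
            return fermentation_scenario(fold=self.scenario.fold, **common)
        if kind == "banded":
            return banded_scenario(
                folds=self.scenario.folds, band_edges_mm=self.scenario.band_edges_mm, **common
            )
        return antibiotic_scenario(**common)
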