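"""Validated run configuration.

One JSON document configures the whole pipeline.  Every default reproduces
the monitoring study's settings: 75 ns track-coincidence window, 8 x 8 x 10
mm voxels with a 100-count eligibility threshold and a 2-sigma Poisson
significance rule, 5 mm depth bins, and seven delivery repetitions summed to
emulate a seven-tracker system.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator


class GeometryConfig(BaseModel):
    layer_separation_mm: float = 20.3
    pixel_pitch_mm: float = 0.055
    active_area_mm: tuple[float, float] = (28.0, 14.0)
    pixels_per_layer: tuple[int, int] = (509, 254)
    sensor_thickness_mm: float = 0.5
    focus_angle_deg: float = 30.0
    front_layer_distance_mm: float = 167.0
    tilt_deg: float = 1.6
    azimuth_deg: float = 90.0

    def to_tracker(self):
        from .geometry import TrackerGeometry

        return TrackerGeometry(
            layer_separation=self.layer_separation_mm,
            pixel_pitch=self.pixel_pitch_mm,
            active_area=tuple(self.active_area_mm),
            pixels_per_layer=tuple(self.pixels_per_layer),
            sensor_thickness=self.sensor_thickness_mm,
            focus_angle_deg=self.focus_angle_deg,
            front_layer_distance=self.front_layer_distance_mm,
            tilt_deg=self.tilt_deg,
            azimuth_deg=self.azimuth_deg,
        )


class ClusteringConfig(BaseModel):
    time_window_ns: float = Field(100.0, gt=0)
    adjacency: Literal[4, 8] = 8


class TrackingConfig(BaseModel):
    window_ns: float = Field(75.0, gt=0)
    wide_angle_deg: float = 45.0  # tracks steeper than this to the focus line are flagged


class GridConfig(BaseModel):
    # voxel centers aligned with the beam axis (x = y = 0)
    origin_mm: tuple[float, float, float] = (-36.0, -36.0, -90.0)
    voxel_size_mm: tuple[float, float, float] = (8.0, 8.0, 10.0)
    shape: tuple[int, int, int] = (9, 9, 18)
    min_count: int = Field(100, ge=0)
    k_sigma: float = Field(2.0, gt=0)
    eligibility: Literal["both", "either", "first"] = "both"
    depth_bin_mm: float = Field(5.0, gt=0)
    miss_distance_cut_mm: float | None = None  # off by default
    regions: dict[str, tuple[float, float]] = {
        "phantom": (-80.0, 80.0),
        "ptv": (-23.0, 23.0),
        "nasopharynx": (-15.0, -5.0),
    }

    @model_validator(mode="after")
    def _positive(self):
        if any(v <= 0 for v in self.voxel_size_mm) or any(s <= 0 for s in self.shape):
            raise ValueError("voxel sizes and shape must be positive")
        return self


class PlanConfig(BaseModel):
    n_layers: int = Field(5, ge=1)
    spots_per_layer: int = Field(40, ge=1)
    n_primaries: int = Field(2000, ge=1)
    energy_min_mev_u: float = 153.0
    energy_max_mev_u: float = 250.0
    spot_spacing_mm: float = 2.0
    spot_duration_ns: float = 5.0e6
    spot_gap_ns: float = 1.0e6
    full_plan: bool = False  # 25 layers x 238 spots, clinical-scale primaries

    @model_validator(mode="after")
    def _energies(self):
        if not (self.energy_min_mev_u < self.energy_max_mev_u):
            raise ValueError("energy_min must be below energy_max")
        return self


class PhantomConfig(BaseModel):
    entry_z_mm: float = -80.0
    exit_z_mm: float = 80.0
    lateral_halfwidth_mm: tuple[float, float] = (75.0, 75.0)
    tissue_density: float = Field(1.0, gt=0)
    density_layers: list[tuple[float, float, float]] = []  # (z0, z1, density)
    insert_z_mm: tuple[float, float] = (-15.0, -5.0)
    insert_lateral_mm: tuple[float, float] = (25.0, 25.0)
    insert_center_mm: tuple[float, float] = (0.0, 0.0)
    insert_delta_density: float = 0.98  # silicone at HU -20 filling the cavity

    @model_validator(mode="after")
    def _inside(self):
        if not (self.entry_z_mm < self.exit_z_mm):
            raise ValueError("entry_z must be below exit_z")
        z0, z1 = self.insert_z_mm
        if not (self.entry_z_mm <= z0 < z1 <= self.exit_z_mm):
            raise ValueError("insert interval must lie inside the phantom")
        return self


class EmissionConfig(BaseModel):
    theta0_rad: float = Field(0.35, gt=0)
    lambda_primary_mm: float = Field(250.0, gt=0)
    lambda_fragment_mm: float = Field(400.0, gt=0)
    beam_sigma_mm: float = Field(2.0, ge=0)
    mcs_sigma_rad: float = Field(0.008, ge=0)
    edep_median_kev: float = Field(40.0, gt=0)
    edep_sigma_log: float = Field(0.5, ge=0)
    range_alpha_mm: float = Field(0.00733, gt=0)
    range_exponent: float = Field(1.77, gt=0)
    toa_jitter_ns: float = Field(3.0, ge=0)


class SyntheticConfig(BaseModel):
    plan: PlanConfig = PlanConfig()
    phantom: PhantomConfig = PhantomConfig()
    emission: EmissionConfig = EmissionConfig()
    n_repetitions: int = Field(7, ge=1)
    seed: int = 0
    importance_sampling: bool = True


class RunConfig(BaseModel):
    geometry: GeometryConfig = GeometryConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    tracking: TrackingConfig = TrackingConfig()
    grid: GridConfig = GridConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration; missing blocks take defaults."""
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(mode="json"), indent=2) + "\n")
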