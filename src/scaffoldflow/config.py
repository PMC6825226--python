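"""Run configuration: YAML schema with explicit unit suffixes.

Every numeric key carries its unit in its name (µm, mm, mPa·s, mL/min …);
values are converted to SI internally. The schema is validated up front —
unknown keys are rejected with the offending names listed — so a run
cannot start from a half-understood configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pipeline import MultiscaleConfig
from .stokes import FluidProps

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FluidSection(_Strict):
    mu_mPa_s: float = Field(1.0, gt=0, description="dynamic viscosity")
    rho_kg_m3: float = Field(1000.0, gt=0, description="density")


class GeneratorSection(_Strict):
    porosity: float = Field(0.8, ge=0.3, le=0.95)
    mean_pore_diameter_um: float = Field(80.0, gt=0)
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = Field(10.0, gt=0)
    seed: int = 1


class GeometrySection(_Strict):
    source: Literal["generate", "file"] = "generate"
    path: Optional[str] = None
    generator: GeneratorSection = Field(default_factory=GeneratorSection)

    @model_validator(mode="after")
    def _check_path(self):
        if self.source == "file" and not self.path:
            raise ValueError("geometry.source='file' requires geometry.path")
        return self


class RVESection(_Strict):
    grid: tuple[int, int] = (1, 1)
    xy_size_um: Optional[float] = Field(None, gt=0)


class MicroSection(_Strict):
    inlet_velocity_um_s: float = Field(500.0, gt=0)
    permeability_probe_dp_Pa: float = Field(0.5, gt=0)
    tol: float = Field(1e-4, gt=0)


class MacroSection(_Strict):
    flow_rate_mL_min: Optional[float] = Field(None, gt=0)
    entrance_heights: float = Field(1.0, ge=0)
    exit_heights: float = Field(1.0, ge=0)
    cells_across_height: int = Field(24, ge=4)
    wall_condition: Literal["no_slip", "free_slip"] = "no_slip"


class WSSSection(_Strict):
    surface_model: Literal["smoothed-normal", "staircase"] = "smoothed-normal"
    bin_width_mPa: float = Field(5.0, gt=0)
    max_mPa: float = Field(100.0, gt=0)
    weighting: Literal["area", "count"] = "area"
    bands_mPa: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.11, 10.0), (0.55, 24.0), (10.0, 30.0)]
    )
    subregion_count: int = Field(5, ge=1)
    subregion_width_um: float = Field(50.0, gt=0)


class RunConfig(_Strict):
    """Top-level configuration of a scaffoldflow run."""

    fluid: FluidSection = Field(default_factory=FluidSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    rve: RVESection = Field(default_factory=RVESection)
    micro: MicroSection = Field(default_factory=MicroSection)
    macro: MacroSection = Field(default_factory=MacroSection)
    wss: WSSSection = Field(default_factory=WSSSection)
    output_dir: str = "scaffoldflow_out"

    def props(self) -> FluidProps:
        return FluidProps(mu=self.fluid.mu_mPa_s * 1e-3, rho=self.fluid.rho_kg_m3)

    def to_multiscale(self) -> MultiscaleConfig:
        """Convert to the SI-unit pipeline configuration."""
        flow_rate = None
        if self.macro.flow_rate_mL_min is not None:
            flow_rate = self.macro.flow_rate_mL_min * 1e-6 / 60.0  # m³/s
        return MultiscaleConfig(
            props=self.props(),
            rve_grid=tuple(self.rve.grid),
            rve_xy_um=self.rve.xy_size_um,
            inlet_velocity=self.micro.inlet_velocity_um_s * 1e-6,
            flow_rate=flow_rate,
            permeability_probe_dp=self.micro.permeability_probe_dp_Pa,
            tol=self.micro.tol,
            macro_cells_across_height=self.macro.cells_across_height,
            macro_wall_condition=self.macro.wall_condition,
            macro_entrance_heights=self.macro.entrance_heights,
            macro_exit_heights=self.macro.exit_heights,
            wss_surface_model=self.wss.surface_model,
            bin_width_mpa=self.wss.bin_width_mPa,
            max_mpa=self.wss.max_mPa,
            weighting=self.wss.weighting,
            subregion_count=self.wss.subregion_count,
            subregion_width_um=self.wss.subregion_width_um,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
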