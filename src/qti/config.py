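"""Pipeline configuration: YAML-backed, schema-validated (pydantic).

The configuration mirrors the processing chain: acquisition schedule,
readout trajectory, view-sharing, subspace reconstruction, parameter
inference, contrast synthesis, and the synthetic phantom that closes the
loop for testing.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Geometry",
    "ScheduleConfig",
    "TrajectoryConfig",
    "ViewShareBlock",
    "SubspaceConfig",
    "InferenceConfig",
    "SynthesisConfig",
    "PhantomConfig",
    "IOConfig",
    "PipelineConfig",
    "load_config",
]


class Geometry(BaseModel):
    """Field of view and matrix; the voxel size must divide exactly."""

    fov_mm: float = 192.0
    matrix: int = 200

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.matrix

    @model_validator(mode="after")
    def _check(self):
        if self.fov_mm <= 0 or self.matrix < 8:
            raise ValueError("fov_mm must be positive and matrix >= 8")
        # the voxel edge must come out exact at micrometer resolution
        # (e.g. 192 mm / 200 -> 0.96 mm), so stated resolutions are honest
        voxel_um = self.fov_mm * 1000.0 / self.matrix
        if abs(voxel_um - round(voxel_um)) > 1e-6:
            raise ValueError(
                f"fov_mm/matrix must divide exactly (got {voxel_um / 1000.0} mm)"
            )
        return self


class ScheduleConfig(BaseModel):
    n_reps: int = 880
    ramp_peak_deg: float = 70.0
    tail_deg: float = 5.0
    ramp_up_frac: float = 0.4
    ramp_down_frac: float = 0.3
    field_strength: Literal["1.5T", "3T"] = "3T"
    readout_family: Literal["spiral", "radial"] = "spiral"
    n_segments: int = 1
    inversion_efficiency: float = 1.0
    dephasing_cycles: float = 2.0


class TrajectoryConfig(BaseModel):
    kind: Literal["radial2d", "spiral2d", "radial3d", "spiral3d"] = "spiral3d"
    n_inplane: Optional[int] = None
    gradient_amplitude_mt_m: float = 10.0
    slew_rate_t_m_s: float = 90.0
    n_samples: Optional[int] = None
    density_exponent: float = 1.0


class ViewShareBlock(BaseModel):
    enabled: bool = True
    full_sample_threshold: float = Field(0.25, gt=0, le=1)
    max_window: int = Field(32, ge=0)
    weight_shape: Literal["triangular", "uniform", "hann"] = "triangular"


class SubspaceConfig(BaseModel):
    rank: int = Field(10, ge=1)
    t1_grid: Literal["default", "reduced"] = "reduced"
    recon_method: Literal["adjoint", "cg"] = "adjoint"
    cg_iters: int = 15


class InferenceConfig(BaseModel):
    method: Literal["multipath", "fwd", "fwd_bck", "dict", "group"] = "multipath"
    epochs: int = 500
    lr: float = 0.005
    batch: int = 100
    dropout: float = 0.9
    dropout_is_keep_prob: bool = True
    n_groups: int = 80
    pretrained_model: Optional[str] = None


class SynthesisConfig(BaseModel):
    contrasts: list[Literal["spgr", "fse", "flair"]] = ["spgr", "fse", "flair"]


class PhantomConfig(BaseModel):
    matrix: int = Field(64, ge=32)
    ndim: Literal[2, 3] = 2
    n_coils: int = Field(1, ge=1)
    snr_db: Optional[float] = None


class IOConfig(BaseModel):
    outdir: str = "qti_out"


class PipelineConfig(BaseModel):
    geometry: Geometry = Geometry()
    schedule: ScheduleConfig = ScheduleConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    viewshare: ViewShareBlock = ViewShareBlock()
    subspace: SubspaceConfig = SubspaceConfig()
    inference: InferenceConfig = InferenceConfig()
    synthesis: SynthesisConfig = SynthesisConfig()
    phantom: PhantomConfig = PhantomConfig()
    io: IOConfig = IOConfig()
    seed: int = 0

    model_config = {"extra": "forbid"}


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML; raises with field-level messages."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(doc)
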