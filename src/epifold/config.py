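"""Validated run configuration (YAML in, fully-resolved echo out).

Every paper-gap default lives here in one place: biochemical rates and
totals, mechanical moduli, tissue layout, numerics, and the coupling
settings.  Unknown keys are rejected; every field is range-checked.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .polarity import PolarityParams


class BiochemistryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    D_A: float = Field(1e-4, ge=0)
    D_P: float = Field(1e-4, ge=0)
    D_B: float = Field(1e-4, ge=0)
    kon_A: float = Field(8.58e-4, ge=0)
    koff_A: float = Field(5.40e-3, ge=0)
    k_AB: float = Field(0.50e-2, ge=0)
    k_AP: float = Field(5.80e-4, ge=0)
    kon_P: float = Field(4.74e-3, ge=0)
    koff_P: float = Field(7.30e-3, ge=0)
    k_PA: float = Field(0.20e-4, ge=0)
    kon_B: float = Field(4.29e-3, ge=0)
    koff_B: float = Field(5.40e-3, ge=0)
    k_BA: float = Field(0.40e-4, ge=0)
    k_BP: float = Field(0.14e-4, ge=0)
    alpha: float = Field(1.0, gt=0)
    beta: float = Field(2.0, gt=0)
    gamma: float = Field(2.0, gt=0)
    zeta: float = Field(2.0, gt=0)
    eps: float = Field(1.0, gt=0)
    A_total: float = Field(1.30e3, ge=0)
    P_total: float = Field(1.00e3, ge=0)
    B_total: float = Field(1.40e3, ge=0)

    def to_params(self) -> PolarityParams:
        return PolarityParams(**self.model_dump())


class MechanicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    eta: float = Field(1.0, gt=0)
    K_V: float = Field(1.0, ge=0)
    V_o: float = Field(1.0, gt=0)
    K_a: float = Field(0.0172, ge=0)
    P_hat_o: float = Field(2.16, gt=0)
    lambda_b: float = Field(0.0477, ge=0)
    lambda_ell: float = Field(0.0207, ge=0)  # per owning cell; shared faces sum


class TissueConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_rings: int = Field(2, ge=0)
    layout: str = "concentric"
    boundary: str = "free"

    @field_validator("layout")
    @classmethod
    def _layout(cls, v):
        if v not in ("concentric", "line"):
            raise ValueError("layout must be 'concentric' or 'line'")
        return v

    @field_validator("boundary")
    @classmethod
    def _boundary(cls, v):
        if v not in ("free", "pin_plane"):
            raise ValueError("boundary must be 'free' or 'pin_plane'")
        return v


class NumericsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_nodes: int = Field(512, ge=8)
    n_nodes_tissue: int = Field(256, ge=8)
    dt: float = Field(0.1, gt=0)
    rd_dt: float = Field(0.05, gt=0)
    fd_step: float = Field(1e-6, gt=0)
    steady_tol: float = Field(1e-9, gt=0)
    force_tol: float = Field(1e-8, gt=0)
    coupling_interval: int = Field(10, ge=1)
    rd_bc: str = "reflect"

    @field_validator("rd_bc")
    @classmethod
    def _bc(cls, v):
        if v not in ("reflect", "periodic"):
            raise ValueError("rd_bc must be 'reflect' or 'periodic'")
        return v


class FeedbackConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c_o: tuple[float, float, float, float] = (0.2, -0.8, 2.0, 2.0)
    sigma: float = Field(0.0, ge=0)
    gain: float = Field(0.02, gt=0)
    threshold_frac: float = Field(0.05, gt=0, lt=1)
    q_floor: float = Field(0.2, gt=0)
    q_cap: float = Field(4.0, gt=0)
    max_dq: float = Field(0.05, gt=0)
    probe_mode: str = "equilibrium"

    @field_validator("probe_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("equilibrium", "step"):
            raise ValueError("probe_mode must be 'equilibrium' or 'step'")
        return v


class PerturbationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    time: float = 0.0
    param: str = "P_total"
    factor: float = 0.9
    cells: str = "initiating"  # initiating | center | all

    @field_validator("param")
    @classmethod
    def _param(cls, v):
        ok = ("P_total", "B_total", "A_total", "K_a", "P_hat_o", "lambda_b", "lambda_ell")
        if v not in ok:
            raise ValueError(f"param must be one of {ok}")
        return v


class RunConfig(BaseModel):
    """Top-level, fully validated configuration of a run."""

    model_config = ConfigDict(extra="forbid")

    biochemistry: BiochemistryConfig = BiochemistryConfig()
    mechanics: MechanicsConfig = MechanicsConfig()
    tissue: TissueConfig = TissueConfig()
    numerics: NumericsConfig = NumericsConfig()
    feedback: FeedbackConfig = FeedbackConfig()
    perturbations: list[PerturbationConfig] = [PerturbationConfig()]
    duration: float = Field(1500.0, gt=0)
    record_every: int = Field(100, ge=1)
    seed: int = 0
    outdir: str = "epifold_out"


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file; an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig(**data)


def echo_config(cfg: RunConfig, outdir) -> None:
    """Write the fully resolved configuration next to the run outputs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(
        json.dumps(cfg.model_dump(), indent=2, default=list))
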