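"""Structured configuration: YAML-backed, validated, unknown keys rejected."""

from __future__ import annotations

import logging
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

logger = logging.getLogger("roomct")

__all__ = [
    "GeometryConfig",
    "HuberConfig",
    "OptimizerConfig",
    "ScannerConfig",
    "Config",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    """Scanner geometry defaults: source angles and FoV resolution presets."""

    sad: float = 570.0
    alpha_lat: float = 90.0
    alpha_pa: float = 180.0
    fov_small_mm: float = 1.0  # small-FoV topogram in-plane resolution
    fov_large_mm: float = 2.0  # large-FoV topogram in-plane resolution

    @field_validator("alpha_lat", "alpha_pa")
    @classmethod
    def _alpha_valid(cls, v):
        if v not in (90.0, 180.0):
            raise ValueError(f"source angle must be 90 or 180 degrees, got {v}")
        return v


class HuberConfig(_Strict):
    """Topogram distortion regression settings."""

    delta: float = 1.0  # Huber transition, mm
    lam: float = 1e-3  # L2 weight on the slope (intercept unpenalized)
    predictor: str = "reference"

    @field_validator("predictor")
    @classmethod
    def _pred_valid(cls, v):
        if v not in ("reference", "topogram"):
            raise ValueError("predictor must be 'reference' or 'topogram'")
        return v


class OptimizerConfig(_Strict):
    """Intensity-registration optimizer settings."""

    bins: int = 50
    simplex_delta: float = 2.0  # initial Nelder-Mead simplex edge, mm
    tolerance: float = 0.1  # parameter convergence tolerance, mm


class ScannerConfig(_Strict):
    """Nominal projection geometry (required for projection calibration)."""

    alpha_deg: float
    sad: float
    col_origin: float
    col_spacing: float
    row_origin: float
    row_spacing: float
    n_rows: int
    n_cols: int


class Config(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    huber: HuberConfig = HuberConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    scanner: Optional[ScannerConfig] = None
    seed: int = 0


def load_config(path=None) -> Config:
    """Load and validate configuration; an empty/missing file yields defaults.

    Unknown keys are rejected.  The fully resolved configuration is logged
    so every run records its settings.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
    cfg = Config(**data)
    logger.info("resolved configuration: %s", cfg.model_dump())
    return cfg
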