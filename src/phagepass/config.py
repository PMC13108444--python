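"""Run configuration: YAML-backed, validated, round-trippable.

An empty config file yields the pure-default scenario: the three reference
genotypes with their tabulated traits under the short-transfer protocol.
Unknown keys are rejected, and validation reports every violation at once.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .core_model import DEFAULT_TYPES, PhageParams
from .regimes import RegimeConfig

__all__ = ["PhageBlock", "RegimeBlock", "ExperimentBlock", "RunConfig",
           "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


class PhageBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    phi: float = Field(ge=0)
    beta: float = Field(default=200.0, ge=0)
    tau: float = Field(default=17.0, gt=0)
    delta: float = Field(default=1.7e-2, ge=0)

    def to_params(self) -> PhageParams:
        return PhageParams(self.label, self.phi, self.beta, self.tau, self.delta)

    @classmethod
    def from_params(cls, p: PhageParams) -> "PhageBlock":
        return cls(label=p.label, phi=p.phi, beta=p.beta, tau=p.tau, delta=p.delta)


class RegimeBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    transfer_duration: float = Field(default=30.0, gt=0)
    n_transfers: int = Field(default=6, ge=1)
    reset_mode: Literal["pfu_reset", "fractional_carryover"] = "fractional_carryover"
    fresh_B: float = Field(default=1e8, ge=0)
    reset_pfu: float = Field(default=1e7, gt=0)
    carryover_fraction: float = Field(default=0.02, gt=0, le=1)
    initial_P: list[float] | None = None
    step: float = Field(default=0.01, gt=0)

    def to_regime(self, n_types: int) -> RegimeConfig:
        initial = self.initial_P
        if initial is None:
            initial = [1e7 / n_types] * n_types
        return RegimeConfig(
            transfer_duration=self.transfer_duration,
            n_transfers=self.n_transfers,
            reset_mode=self.reset_mode,
            fresh_B=self.fresh_B,
            reset_pfu=self.reset_pfu,
            carryover_fraction=self.carryover_fraction,
            initial_P=tuple(initial),
            step=self.step,
        )


class ExperimentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    phi_min: float = Field(default=4e-12, gt=0)
    phi_max: float = Field(default=4e-9, gt=0)
    n_phi: int = Field(default=60, ge=2)
    moi: float = Field(default=0.1, gt=0)
    pattern_tol: float = Field(default=0.01, gt=0)
    burst_threshold: float = Field(default=0.01, gt=0, lt=1)
    dilution_factors: list[float] = Field(default_factory=lambda: [50.0, 500.0, 2000.0])
    transfer_times: list[float] = Field(default_factory=lambda: [20.0, 40.0, 80.0, 160.0, 240.0])
    landscape_dilutions: list[float] = Field(default_factory=lambda: [10.0, 50.0, 250.0, 1000.0, 5000.0])
    landscape_transfers: int = Field(default=100, ge=1)
    landscape_step: float = Field(default=0.01, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scenario: str = "regime"
    seed: int = 0
    out_dir: str = "phagepass_out"
    phages: list[PhageBlock] = Field(
        default_factory=lambda: [PhageBlock.from_params(p) for p in DEFAULT_TYPES]
    )
    regime: RegimeBlock = Field(default_factory=RegimeBlock)
    experiment: ExperimentBlock = Field(default_factory=ExperimentBlock)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if len(self.phages) == 0:
            raise ValueError("at least one phage block is required")
        labels = [p.label for p in self.phages]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate phage labels: {labels}")
        return self

    def params(self) -> list[PhageParams]:
        return [p.to_params() for p in self.phages]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file produces the all-defaults configuration.  Schema errors
    are collected and reported together.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration:\n" + "\n".join(lines)) from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (lossless round trip)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
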