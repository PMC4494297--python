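"""Validated run configuration.

A run is configured from a YAML file (or keyword overrides).  Unknown
keys are rejected so typos fail before any computation.  The
``inputs: fixtures`` sentinel selects the packaged 2001 study tables;
otherwise cohort/diet/crop CSV paths drive a bottom-up inventory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

FIXTURES_SENTINEL = "fixtures"


class GwpConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ch4: float = 21.0
    n2o: float = 310.0


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cohorts: Path
    diets: Path
    crops: Path


class RunConfig(BaseModel):
    """Configuration for inventory and study runs."""

    model_config = ConfigDict(extra="forbid")

    inputs: str | InputPaths = FIXTURES_SENTINEL
    fraction: float = Field(default=0.10, ge=0.0, lt=1.0)
    benchmark_years: float = Field(default=40.0, gt=0.0)
    decay_fraction_at_horizon: float = Field(default=0.60, gt=0.0, lt=1.0)
    gwp: GwpConfig = GwpConfig()
    ef_organic: float = Field(default=0.0125, gt=0.0, lt=1.0)
    ef_synthetic: float = Field(default=0.0125, gt=0.0, lt=1.0)
    sales_adjustment: float = Field(default=1.0, ge=0.0)
    seed: int = 0
    out_dir: Path = Path("ulicees-out")
    log_level: str = "INFO"

    @field_validator("inputs")
    @classmethod
    def _check_sentinel(cls, v):
        if isinstance(v, str) and v != FIXTURES_SENTINEL:
            raise ValueError(
                f"inputs must be {FIXTURES_SENTINEL!r} or a path mapping"
            )
        return v

    @property
    def uses_fixtures(self) -> bool:
        return isinstance(self.inputs, str)

    def config_hash(self) -> str:
        """Stable digest of the configuration, logged with every run."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(**raw)

    def to_yaml(self, path: Optional[str | Path] = None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"),
                              sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
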