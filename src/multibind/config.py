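"""Run configuration: schema-validated YAML with strict unknown-key rejection.

All physical constants and model conventions live here rather than at
call sites, so a single config file pins an entire analysis run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "WLCConfig", "ThermoConfig", "InputConfig", "SpeciationConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WLCConfig(_Strict):
    persistence_length_A: float = Field(3.0, gt=0, description="persistence length, Angstrom")
    residue_contour_A: float = Field(3.8, gt=0, description="contour length per residue, Angstrom")


class ThermoConfig(_Strict):
    temperature_K: float = Field(298.0, gt=0)
    gas_constant_kcal: float = Field(1.987e-3, gt=0)


class InputConfig(_Strict):
    fasta: str | None = None
    affinities_nsh3_csv: str | None = None
    affinities_csh3_csv: str | None = None
    ceff_csv: str | None = None
    motifs: list[str] | None = None


class SpeciationConfig(_Strict):
    total_G_M: float | None = Field(None, ge=0)
    total_S_M: float | None = Field(None, ge=0)
    sweep_species: Literal["G", "S"] = "G"
    sweep_ratios: list[float] | None = None


class RunConfig(_Strict):
    """Top-level configuration for :func:`multibind.pipeline.run_pipeline`."""

    wlc: WLCConfig = WLCConfig()
    thermo: ThermoConfig = ThermoConfig()
    convention: Literal["paper", "strict"] = "paper"
    substitutions: dict[str, str] = Field(default_factory=lambda: {"RP": "P3"})
    inputs: InputConfig = InputConfig()
    speciation: SpeciationConfig = SpeciationConfig()
    out_dir: str = "multibind_out"
    seed: int = 0
    verbosity: int = 1

    def digest(self) -> str:
        """Stable hash of the full configuration, embedded in every report."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
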