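"""Validated run configuration for the pipeline and CLI.

A single JSON (or YAML-compatible dict) document configures acquisition
defaults, the solvent context, decision thresholds and seeds.  Unknown keys
are rejected with their location so typos never become silent defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .hydrodynamics import SolventContext, TSP_REFERENCE_D, WATER_VISCOSITY_298K
from .pgse import GAMMA_1H, AcquisitionParams

__all__ = ["AcquisitionConfig", "SolventConfig", "Thresholds", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Strict):
    gamma: float = Field(default=GAMMA_1H, gt=0)
    #: single-lobe gradient pulse length, s (vendor P30)
    gradient_pulse_s: float = Field(default=0.75e-3, gt=0)
    #: diffusion time Delta, s (vendor D20)
    diffusion_time_s: float = Field(default=0.1, gt=0)
    #: "bipolar": effective delta = 2 x pulse; "monopolar": delta = pulse
    delta_convention: str = "bipolar"

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionConfig":
        if self.delta_convention not in ("bipolar", "monopolar"):
            raise ValueError("delta_convention must be 'bipolar' or 'monopolar'")
        return self

    def to_params(self) -> AcquisitionParams:
        delta = (
            2.0 * self.gradient_pulse_s
            if self.delta_convention == "bipolar"
            else self.gradient_pulse_s
        )
        return AcquisitionParams(
            gamma=self.gamma, little_delta=delta, big_delta=self.diffusion_time_s
        )


class SolventConfig(_Strict):
    temperature_K: float = Field(default=298.0, gt=0)
    viscosity_pa_s: float = Field(default=WATER_VISCOSITY_298K, gt=0)
    tsp_reference_D_m2_per_s: float = Field(default=TSP_REFERENCE_D, gt=0)

    def to_context(self) -> SolventContext:
        return SolventContext(
            temperature=self.temperature_K,
            viscosity=self.viscosity_pa_s,
            tsp_reference_D=self.tsp_reference_D_m2_per_s,
        )


class Thresholds(_Strict):
    activity_log10: float = 5.0
    bound_percent_veto: float = Field(default=50.0, ge=0, le=100)
    clamp_tolerance: float = Field(default=0.05, ge=0)
    countable_plate_min: int = Field(default=30, ge=1)
    countable_plate_max: int = Field(default=300, ge=1)
    #: effective HEC binding-site mass, g/mol (HEC is polymeric; the molar
    #: basis of a mg/mL loading is a modelling choice)
    hec_mass_per_site_g_per_mol: float = Field(default=250.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "Thresholds":
        if self.countable_plate_max <= self.countable_plate_min:
            raise ValueError("countable_plate_max must exceed countable_plate_min")
        return self


class RunConfig(_Strict):
    acquisition: AcquisitionConfig = AcquisitionConfig()
    solvent: SolventConfig = SolventConfig()
    thresholds: Thresholds = Thresholds()
    seed: int = Field(default=0, ge=0)
    output_dir: str = "cpcdosy_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        return cls.model_validate(json.loads(text))

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
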