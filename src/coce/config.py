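"""Validated pipeline configuration.

One document collects every tunable of the pipeline -- optics, strain
estimator window and lag, silicone calibration, stress standardization,
stiffness class boundaries and the subtype-feature constants -- so a run is
fully described by (config, seed, input).  Unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .segmentation import ClassRanges


class PipelineConfig(BaseModel):
    model_config = {"extra": "forbid"}

    # optics / sampling
    wavelength_um: float = Field(1.31, gt=0)
    refractive_index: float = Field(1.4, gt=0)
    axial_pixel_um: float = Field(4.0, gt=0)
    lateral_pixel_um: float = Field(4.0, gt=0)
    psf_axial_um: float = Field(15.0, gt=0)
    psf_lateral_um: float = Field(25.0, gt=0)

    # strain estimator
    window_axial_um: float = Field(100.0, gt=0)
    window_lateral_um: float = Field(100.0, gt=0)
    axial_lag_px: int = Field(3, ge=1)

    # stress calibration and standardization
    E_sil_kPa: float = Field(100.0, gt=0)
    stress_window_kPa: tuple[float, float] = (3.0, 5.0)
    standardized_stress_kPa: float = Field(4.0, gt=0)
    max_modulus_kPa: float = Field(5000.0, gt=0)
    per_column_stress: bool = True

    # segmentation / subtype features
    class_ranges: ClassRanges = Field(default_factory=ClassRanges)
    depth_limit_um: float = Field(500.0, gt=0)
    min_gland_area_um2: float = Field(110.0 * 110.0, gt=0)
    min_roi_area_um2: float = Field(110.0 * 110.0, gt=0)
    gland_max_coverage: float = Field(0.7, gt=0, le=1)
    loss_floor: float = Field(0.02, ge=0, le=1)

    # acquisition defaults for simulation
    n_frames: int = Field(100, ge=2)
    max_stress_kPa: float = Field(6.0, gt=0)
    snr_db: float | None = 25.0
    seed: int = 0

    @model_validator(mode="after")
    def _window_contains_standard(self) -> "PipelineConfig":
        lo, hi = self.stress_window_kPa
        if not (0 < lo < self.standardized_stress_kPa < hi):
            raise ValueError("stress window must bracket the standardized "
                             "stress")
        return self

    # -- serialization ----------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        doc = json.loads(self.model_dump_json())
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
        else:
            path.write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        doc = (yaml.safe_load(text) if path.suffix in (".yml", ".yaml")
               else json.loads(text))
        return cls.model_validate(doc)
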