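"""Study configuration with validation and lossless file round-tripping."""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, field_validator


class StudyConfig(BaseModel):
    """Assay constants, fit thresholds and noise defaults for a pipeline run.

    Defaults mirror the standard fluorometric BNA protocol: MUNANA substrate
    with Km = 100 µM, 1-min reads over 20 min at 0.02 unit/mL enzyme.
    """

    km: float = Field(100.0, gt=0, description="substrate Km, uM")
    read_interval_min: float = Field(1.0, gt=0)
    read_duration_min: float = Field(20.0, gt=0)
    enzyme_ref: float = Field(0.02, gt=0, description="reference enzyme load, unit/mL")
    linearity_r2: float = Field(0.98, gt=0, le=1.0)
    mode_score_margin: float = Field(2.0, gt=0)
    intercept_z: float = Field(2.0, gt=0)
    cv: float = Field(0.02, ge=0)
    replicates: int = Field(3, ge=1)
    seed: int = 0
    concentration_unit: str = "uM"

    @field_validator("concentration_unit")
    @classmethod
    def _known_unit(cls, v: str) -> str:
        if v not in ("uM", "nM", "mM"):
            raise ValueError(f"unsupported concentration unit {v!r}")
        return v

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.model_validate(data)
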