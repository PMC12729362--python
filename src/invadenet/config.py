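"""Run configuration: YAML-backed, schema-validated, hash-stamped.

Every tunable of a pipeline run lives here with an explicit default, and
the SHA-256 hash of the canonical JSON form is stamped into all artifacts
so outputs from different configurations cannot be mixed silently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field

__all__ = ["RunConfig", "run_config_hash"]


class PhantomSection(BaseModel):
    n_patients: int = 200
    image_size: int = 64
    class_fraction_invasive: float = 0.26
    rician_sigma: float = 5.0
    gaussian_sigma: float = 3.0
    missing_phase_prob: float = 0.05


class ModelSection(BaseModel):
    scale: Literal["desk", "full"] = "desk"
    variant: Literal["full", "mhmc_only", "fwam_only"] = "full"


class TrainSection(BaseModel):
    lr: float = 1.5e-3
    batch_size: int = 8
    max_epochs: int = 40
    patience: int = 12
    weight_decay: float = 1e-3
    oversample_minority: bool = True
    input_jitter: float = 0.1
    dihedral_augment: bool = True


class EvalSection(BaseModel):
    bootstrap_B: int = 500
    threshold: float = 0.5


class ExplainSection(BaseModel):
    branch_kernel: int = 3
    n_examples: int = 2
    alpha: float = 0.4


class RunConfig(BaseModel):
    seed: int = 7
    out_dir: str = "runs/default"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    explain: ExplainSection = Field(default_factory=ExplainSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        return cls.model_validate(yaml.safe_load(p.read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def run_config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration; the output location does not
    change what is computed and is excluded."""
    payload = cfg.model_dump()
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
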