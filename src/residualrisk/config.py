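"""Run configuration: one structured file drives the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .simulate import EffectDistribution
from .synth import CohortSpec, default_cohort_spec

__all__ = ["CohortSource", "RunConfig", "load_config", "config_hash", "write_provenance"]


class CohortSource(BaseModel):
    """Exactly one of: a cohort CSV path, or a synthetic-cohort recipe."""

    model_config = {"frozen": True}

    path: Optional[str] = None
    synthetic: Optional[dict] = None  # overrides onto the default CohortSpec (n, seed)

    @model_validator(mode="after")
    def _exactly_one(self) -> "CohortSource":
        if (self.path is None) == (self.synthetic is None):
            raise ValueError("configure exactly one cohort source: 'path' or 'synthetic'")
        return self

    def cohort_spec(self) -> CohortSpec:
        if self.synthetic is None:
            raise ValueError("cohort source is a file, not a synthetic spec")
        allowed = {"n", "seed"}
        extra = set(self.synthetic) - allowed
        if extra:
            raise ValueError(f"unsupported synthetic-cohort overrides: {sorted(extra)}")
        return default_cohort_spec(**self.synthetic)


class RunConfig(BaseModel):
    model_config = {"frozen": True}

    cohort: CohortSource
    coefficients: Optional[str] = None  # None -> packaged default
    scenarios: tuple[str, ...] = ("ACC_AHA_70", "ESC_EAS_55", "EXPLORATORY_40")
    effect: EffectDistribution = EffectDistribution()
    n_replicates: int = Field(default=100, ge=1)
    seed: int = 0
    output_dir: str = "out"


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_provenance(config: RunConfig, path: Path, command: str) -> Path:
    """Sidecar recording what produced an output directory (no timestamps,
    so repeated identical runs are byte-identical)."""
    from . import __version__

    sidecar = {
        "command": command,
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
    }
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path
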