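"""Structured run configuration (YAML) for the command-line interface.

Every tunable of the pipeline lives here; files are validated strictly
(unknown keys are rejected) before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pydantic
import yaml

from .curation import SplitSpec
from .exceptions import ConfigurationError
from .kernels import LAKernelParams
from .pipeline import DEFAULT_D_M, DEFAULT_M_M, PipelineConfig


class _Strict(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class DataConfig(_Strict):
    interactions: str
    molecules: str | None = None
    proteins: str | None = None
    format: str = "tsv"


class KernelConfig(_Strict):
    beta: float = 0.5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    substitution: str = "BLOSUM62"
    log_transform: bool = True
    unknown_score: float = -4.0


class FeatureConfig(_Strict):
    n_bits: int = 1024
    radius: int = 2
    m_M: int = DEFAULT_M_M
    d_M: int = DEFAULT_D_M
    m_P: int | None = None  # None = exact protein map (all landmarks)
    d_P: int | None = None
    center_molecules: bool = True
    center_proteins: bool = True
    normalize: bool = True


class SvmConfig(_Strict):
    lam: float = 1e-6
    lambda_grid: list[float] | None = None  # None = the default CV grid
    max_iter: int = 200
    tol: float = 1e-6
    calibrate: bool = True


class SplitConfig(_Strict):
    scenario: str = "random"
    n_folds: int = 5
    seed: int = 0


class RunConfig(_Strict):
    """Top-level schema of a run configuration file."""

    data: DataConfig | None = None
    output: str = "komet_out"
    kernel: KernelConfig = pydantic.Field(default_factory=KernelConfig)
    features: FeatureConfig = pydantic.Field(default_factory=FeatureConfig)
    svm: SvmConfig = pydantic.Field(default_factory=SvmConfig)
    split: SplitConfig = pydantic.Field(default_factory=SplitConfig)
    seed: int = 0
    verbose: bool = False

    def la_params(self) -> LAKernelParams:
        k = self.kernel
        return LAKernelParams(
            beta=k.beta,
            gap_open=k.gap_open,
            gap_extend=k.gap_extend,
            substitution=k.substitution,
            log_transform=k.log_transform,
            unknown_score=k.unknown_score,
        )

    def pipeline_config(self) -> PipelineConfig:
        f, s = self.features, self.svm
        return PipelineConfig(
            n_bits=f.n_bits,
            radius=f.radius,
            m_M=f.m_M,
            d_M=f.d_M,
            m_P=f.m_P,
            d_P=f.d_P,
            la_params=self.la_params(),
            center_molecules=f.center_molecules,
            center_proteins=f.center_proteins,
            normalize=f.normalize,
            lam=s.lam,
            max_iter=s.max_iter,
            tol=s.tol,
            calibrate=s.calibrate,
        )

    def split_spec(self) -> SplitSpec:
        return SplitSpec(
            scenario=self.split.scenario,
            n_folds=self.split.n_folds,
            seed=self.split.seed,
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(p.read_text()) or {}
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"unreadable YAML {path}: {exc}") from exc
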