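"""Validated run configuration for the pipeline.

A YAML file is validated against a strict schema (unknown keys rejected)
before any stage runs; every stage draws its randomness from the single
top-level seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_founders: int = 40
    years: int = 45
    start_year: int = 1970
    birth_prob: float = Field(0.22, ge=0.0, le=1.0)
    female_emigration_prob: float = Field(0.5, ge=0.0, le=1.0)
    annual_immigration: float = Field(1.2, ge=0.0)
    avoidance_gamma: float = Field(0.0, ge=0.0)
    n_sites: int = Field(10_000, ge=1)
    mean_depth: float = Field(8.0, gt=0.0)
    base_error: float = Field(0.01, ge=0.0, lt=0.5)
    panel_size: int = Field(60, ge=2)
    panel_depth: float = Field(15.0, gt=0.0)


class FilterSection(_Strict):
    min_ind_frac: float = Field(0.9, ge=0.0, le=1.0)
    hwe_alpha: float = Field(0.001, ge=0.0, le=1.0)
    maf_min: float = Field(0.05, ge=0.0, lt=0.5)


class RelateSection(_Strict):
    tol: float = Field(1e-6, gt=0.0)
    max_iter: int = Field(500, ge=1)
    n_restarts: int = Field(2, ge=0)


class PairsSection(_Strict):
    window_days: int = Field(15, ge=0)


class CrypticSection(_Strict):
    low: float = Field(0.1, ge=0.0, le=1.0)
    high: float = Field(0.35, ge=0.0, le=1.0)


class PriorSection(_Strict):
    alpha_mean: float = -4.0
    alpha_sd: float = Field(1.5, gt=0.0)
    beta_sd: float = Field(1.0, gt=0.0)
    sigma_rate: float = Field(1.0, gt=0.0)
    log_phi_mean: float = 3.0
    log_phi_sd: float = Field(2.0, gt=0.0)


class MCMCSection(_Strict):
    chains: int = Field(4, ge=2)
    warmup: int = Field(800, ge=10)
    draws: int = Field(500, ge=10)
    target_accept: float = Field(0.85, gt=0.0, lt=1.0)


class RunConfig(_Strict):
    """Top-level pipeline configuration (one seed drives every stage)."""

    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateSection = SimulateSection()
    filters: FilterSection = FilterSection()
    relate: RelateSection = RelateSection()
    pairs: PairsSection = PairsSection()
    cryptic: CrypticSection = CrypticSection()
    priors: PriorSection = PriorSection()
    mcmc: MCMCSection = MCMCSection()


def load_config(path: Optional[str]) -> RunConfig:
    """Load and validate a YAML config; defaults when path is None."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
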