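"""Run configuration: schema-validated YAML with paper-default values.

Every default equals the published model value where one exists (compound
physicochemistry, cytosolic Vmax/Km, liver tissue scalar 11, adult renal
clearance 3.3 L/h, neonatal Kp scalar 0.44, ontogeny and GFR-polynomial
coefficients); unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ValidationError

from .clearance import ADULT_RENAL_CL_L_H, LIVER_TISSUE_SCALAR
from .engine import DEFAULT_INFUSION_H, SolverConfig
from .ontogeny import AdhOntogenyParams, GfrPolynomial
from .saturation import DOSE_GRID_MG_KG, PLAT_MG_L, STANDARD_INTERVALS_H
from .units import CompoundParams, PG_DEFAULTS

__all__ = ["RunConfig", "load_config", "ConfigError", "config_manifest"]


class ConfigError(ValueError):
    pass


class KineticsBlock(BaseModel):
    vmax_invitro: float = 1.57  # nmol/min/mg cytosolic protein
    km_mm: float = 25.1  # mM

    model_config = {"extra": "forbid", "frozen": True}


class PopulationBlock(BaseModel):
    group: Literal["adult", "term_neonate"] = "adult"
    n_subjects: int = 200
    zero_variability: bool = False

    model_config = {"extra": "forbid", "frozen": True}


class DistributionBlock(BaseModel):
    kp_scalar_adult: float = 1.0
    kp_scalar_neonate: float = 0.44

    model_config = {"extra": "forbid", "frozen": True}


class ClearanceBlock(BaseModel):
    tissue_scalar_liver: float = LIVER_TISSUE_SCALAR
    renal_cl_adult: float = ADULT_RENAL_CL_L_H  # L/h

    model_config = {"extra": "forbid", "frozen": True}


class RegimenBlock(BaseModel):
    route: Literal["iv_infusion", "iv_bolus", "oral"] = "iv_infusion"
    dose_per_event: float = 0.75  # mg/kg
    interval: float = 24.0  # h
    n_doses: int | None = None  # None -> enough to reach steady state
    infusion_duration: float = DEFAULT_INFUSION_H

    model_config = {"extra": "forbid", "frozen": True}


class SolverBlock(BaseModel):
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt: float = 0.1

    model_config = {"extra": "forbid", "frozen": True}

    def to_solver_config(self) -> SolverConfig:
        return SolverConfig(rtol=self.rtol, atol=self.atol, output_dt=self.output_dt)


class AnalysisBlock(BaseModel):
    dose_grid: tuple[float, ...] = DOSE_GRID_MG_KG
    plat: float = PLAT_MG_L
    intervals: tuple[float, ...] = STANDARD_INTERVALS_H
    r2_threshold: float = 0.98
    deviation_pct: float = 1.0

    model_config = {"extra": "forbid", "frozen": True}


class RunConfig(BaseModel):
    compound: CompoundParams = PG_DEFAULTS
    kinetics: KineticsBlock = KineticsBlock()
    population: PopulationBlock = PopulationBlock()
    ontogeny: AdhOntogenyParams = AdhOntogenyParams()
    gfr_poly: GfrPolynomial = GfrPolynomial()
    distribution: DistributionBlock = DistributionBlock()
    clearance: ClearanceBlock = ClearanceBlock()
    regimen: RegimenBlock = RegimenBlock()
    solver: SolverBlock = SolverBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    seed: int = 0
    output_dir: str = "pgpbpk_out"

    model_config = {"extra": "forbid", "frozen": True}

    @property
    def kp_scalar(self) -> float:
        if self.population.group == "term_neonate":
            return self.distribution.kp_scalar_neonate
        return self.distribution.kp_scalar_adult


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigError(f"config file is empty: {path}")
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        offenders = sorted(
            {".".join(str(p) for p in e["loc"]) for e in exc.errors()}
        )
        raise ConfigError(
            f"invalid configuration ({path}): offending keys: {offenders}"
        ) from exc


def config_manifest(cfg: RunConfig) -> dict:
    """Reproducibility manifest: config hash, seed, package versions."""
    import numpy
    import scipy

    from . import __version__

    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": cfg.seed,
        "pgpbpk_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
    }
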