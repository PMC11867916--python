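"""Virtual adults and term neonates.

Generates individuals with anthropometry, organ volumes and blood flows by
sampling lognormal interindividual variability around a documented reference
physiology (shipped as editable YAML).  Organ volumes scale with body
weight; cardiac output and blood flows scale allometrically (weight^0.75).
Neonatal GFR is derived from each subject's body surface area through the
quadratic maturation polynomial; adult renal clearance is handled by the
clearance module via a per-subject kidney-function multiplier sampled here.

With all coefficients of variation set to zero, sampling is degenerate and
returns the reference individual exactly — a property the tests rely on.
"""

from __future__ import annotations

import importlib.resources
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .ontogeny import (
    ADH_ONTOGENY_DEFAULTS,
    GFR_POLY_DEFAULTS,
    AdhOntogenyParams,
    GfrPolynomial,
    adh_fraction,
    gfr_from_bsa,
)

__all__ = [
    "PopulationSpec",
    "Subject",
    "TISSUES",
    "body_surface_area",
    "sample_subject",
    "generate_population",
    "population_spec",
    "population_to_frame",
]

#: Perfusion-limited tissue compartments of the whole-body model.
TISSUES = (
    "lung",
    "liver",
    "kidney",
    "muscle",
    "adipose",
    "skin",
    "brain",
    "heart",
    "gut",
    "spleen",
    "bone",
    "rest",
)

LIVER_DENSITY_G_PER_ML = 1.05


def _load_physiology() -> dict:
    ref = importlib.resources.files("pgpbpk.data") / "physiology.yaml"
    return yaml.safe_load(ref.read_text())


class PopulationSpec(BaseModel):
    """Specification of one virtual-population group."""

    group: Literal["adult", "term_neonate"]
    n_subjects: int = 200
    age_range: tuple[float, float] = (0.0, 0.0)
    reference_weight: float  # kg
    reference_height: float  # cm
    cardiac_output_ref: float  # L/h
    hematocrit: float
    cppgl: float  # mg cytosolic protein / g liver
    blood_volume_fraction: float
    organ_volume_fractions: Mapping[str, float]
    blood_flow_fractions: Mapping[str, float]
    variability_cv: Mapping[str, float] = {}
    seed: int = 0
    adh_ontogeny: AdhOntogenyParams = ADH_ONTOGENY_DEFAULTS
    gfr_poly: GfrPolynomial = GFR_POLY_DEFAULTS

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        vols = self.organ_volume_fractions
        missing = set(TISSUES) - set(vols)
        if missing:
            raise ValueError(f"missing organ volume fractions: {sorted(missing)}")
        total = sum(vols.values()) + self.blood_volume_fraction
        if total > 1.0 + 1e-9:
            raise ValueError(f"volume fractions sum to {total:.3f} > 1")
        flows = self.blood_flow_fractions
        expected = {t for t in TISSUES if t != "lung"} - {"liver"} | {"liver_arterial"}
        if set(flows) != expected:
            raise ValueError(
                f"blood flow fractions must cover {sorted(expected)}, got {sorted(flows)}"
            )
        fsum = sum(flows.values())
        if abs(fsum - 1.0) > 1e-6:
            raise ValueError(f"blood flow fractions sum to {fsum:.6f} != 1")
        if any(cv < 0 for cv in self.variability_cv.values()):
            raise ValueError("CVs must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        return self


class Subject(BaseModel):
    """One virtual individual, fully resolved to absolute volumes and flows.

    ``blood_flows`` holds tissue inflows in L/h on a whole-blood basis;
    ``liver`` is the *total* liver inflow (hepatic artery + portal from gut
    and spleen) and ``lung`` equals cardiac output (lung in series).
    """

    group: Literal["adult", "term_neonate"]
    age: float  # years
    weight: float  # kg
    height: float  # cm
    bsa: float  # m^2
    organ_volumes: Mapping[str, float]  # L, includes venous/arterial blood
    blood_flows: Mapping[str, float]  # L/h
    liver_mass: float  # g
    cppgl: float  # mg/g
    gfr: float  # mL/min (0 for adults: they use the fixed renal clearance)
    renal_multiplier: float = 1.0  # adult kidney-function variability
    hematocrit: float
    adh_maturation: float  # fraction of adult ADH activity

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "Subject":
        if any(v <= 0 for v in self.organ_volumes.values()):
            raise ValueError("all organ volumes must be positive")
        if any(q <= 0 for q in self.blood_flows.values()):
            raise ValueError("all blood flows must be positive")
        expected_mass = self.organ_volumes["liver"] * LIVER_DENSITY_G_PER_ML * 1000.0
        if abs(self.liver_mass - expected_mass) > 1e-6 * expected_mass:
            raise ValueError("liver_mass inconsistent with liver volume at 1.05 g/mL")
        if abs(self.bsa - body_surface_area(self.weight, self.height)) > 1e-9:
            raise ValueError("bsa inconsistent with weight/height formula")
        return self

    @property
    def cardiac_output(self) -> float:
        return self.blood_flows["lung"]


def body_surface_area(weight: float, height: float) -> float:
    """Haycock body surface area (m²) from weight (kg) and height (cm).

    Chosen because a single formula remains valid from term neonates to
    adults: BSA = 0.024265 * W^0.5378 * H^0.3964.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.024265 * weight**0.5378 * height**0.3964


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal factor with median 1 and the given CV."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def sample_subject(spec: PopulationSpec, rng: np.random.Generator) -> Subject:
    """Draw one virtual individual from the population specification."""
    cv = spec.variability_cv
    lo, hi = spec.age_range
    age = float(spec.age_range[0]) if hi <= lo else float(rng.uniform(lo, hi))
    weight = spec.reference_weight * _lognormal(rng, cv.get("weight", 0.0))
    height = spec.reference_height * _lognormal(rng, cv.get("height", 0.0))
    bsa = body_surface_area(weight, height)

    volumes: dict[str, float] = {}
    for tissue in TISSUES:
        v = spec.organ_volume_fractions[tissue] * weight
        if tissue == "liver":
            v *= _lognormal(rng, cv.get("liver", 0.0))
        volumes[tissue] = v
    blood = spec.blood_volume_fraction * weight
    volumes["venous"] = blood * 2.0 / 3.0
    volumes["arterial"] = blood / 3.0

    co = spec.cardiac_output_ref * (weight / spec.reference_weight) ** 0.75
    flows = {t: f * co for t, f in spec.blood_flow_fractions.items()}
    flows["liver"] = flows.pop("liver_arterial") + flows["gut"] + flows["spleen"]
    flows["lung"] = co

    cppgl = spec.cppgl * _lognormal(rng, cv.get("cppgl", 0.0))
    renal_mult = _lognormal(rng, cv.get("renal", 0.0))
    gfr = gfr_from_bsa(bsa, spec.gfr_poly) if spec.group == "term_neonate" else 0.0

    return Subject(
        group=spec.group,
        age=age,
        weight=weight,
        height=height,
        bsa=bsa,
        organ_volumes=volumes,
        blood_flows=flows,
        liver_mass=volumes["liver"] * LIVER_DENSITY_G_PER_ML * 1000.0,
        cppgl=cppgl,
        gfr=gfr,
        renal_multiplier=renal_mult,
        hematocrit=spec.hematocrit,
        adh_maturation=adh_fraction(age, spec.adh_ontogeny),
    )


def generate_population(spec: PopulationSpec) -> list[Subject]:
    """Reproducible list of ``spec.n_subjects`` virtual individuals."""
    rng = np.random.default_rng(spec.seed)
    return [sample_subject(spec, rng) for _ in range(spec.n_subjects)]


def population_spec(
    group: Literal["adult", "term_neonate"],
    n_subjects: int = 200,
    seed: int = 0,
    zero_variability: bool = False,
    **overrides,
) -> PopulationSpec:
    """Build a :class:`PopulationSpec` from the shipped reference physiology."""
    ref = _load_physiology()[group]
    cv = {} if zero_variability else dict(ref["variability_cv"])
    kwargs = dict(
        group=group,
        n_subjects=n_subjects,
        age_range=(ref["age"], ref["age"]),
        reference_weight=ref["reference_weight"],
        reference_height=ref["reference_height"],
        cardiac_output_ref=ref["cardiac_output_ref"],
        hematocrit=ref["hematocrit"],
        cppgl=ref["cppgl"],
        blood_volume_fraction=ref["blood_volume_fraction"],
        organ_volume_fractions=ref["organ_volume_fractions"],
        blood_flow_fractions=ref["blood_flow_fractions"],
        variability_cv=cv,
        seed=seed,
    )
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


def reference_subject(group: Literal["adult", "term_neonate"]) -> Subject:
    """The group's reference individual (all variability switched off)."""
    spec = population_spec(group, n_subjects=1, zero_variability=True)
    return generate_population(spec)[0]


def population_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Flatten a population to a tidy table (one row per subject) for audit."""
    rows = []
    for i, s in enumerate(subjects):
        row = {
            "subject": i,
            "group": s.group,
            "age_y": s.age,
            "weight_kg": s.weight,
            "height_cm": s.height,
            "bsa_m2": s.bsa,
            "liver_mass_g": s.liver_mass,
            "cppgl_mg_g": s.cppgl,
            "gfr_ml_min": s.gfr,
            "adh_maturation": s.adh_maturation,
            "cardiac_output_l_h": s.cardiac_output,
        }
        rows.append(row)
    return pd.DataFrame(rows)
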