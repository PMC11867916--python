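"""In-vitro-to-in-vivo extrapolation of saturable hepatic clearance and
renal clearance.

The whole-liver metabolic capacity is scaled up from the cytosolic assay:

    Vmax_total [mg/h] = Vmax_invitro [nmol/min/mg]
                        x CPPGL [mg cytosolic protein / g liver]
                        x liver mass [g]
                        x tissue scalar (11, recovering whole-organ activity
                          per unit enzyme relative to the cytosol prep)
                        x ADH maturation fraction (1 in adults, 0.18 at birth)
                        x 60 x MW x 1e-6   (nmol/min -> mg/h)

Saturable elimination follows Michaelis-Menten kinetics driven by the
unbound plasma-equivalent concentration leaving the well-stirred liver
(venous-equilibrium convention); Km is converted once to mass units and
treated as an unbound aqueous value (cytosol incubation binding assumed
negligible, consistent with fu_p = 0.99).

Renal clearance: adults use the fixed literature value of 3.3 L/h applied
to the plasma concentration entering the kidney (45% of the published total
systemic clearance); neonates use filtration clearance, GFR x fu_B x blood
concentration, with GFR from the body-surface-area polynomial.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, model_validator

from .population import Subject
from .units import CompoundParams, molar_to_mass_conc, unbound_blood_fraction

__all__ = [
    "HepaticClearanceParams",
    "RenalClearanceParams",
    "LIVER_TISSUE_SCALAR",
    "ADULT_RENAL_CL_L_H",
    "whole_liver_vmax",
    "hepatic_elimination_rate",
    "renal_elimination_rate",
    "hepatic_params_for",
    "renal_params_for",
    "well_stirred_hepatic_blood_cl",
]

LIVER_TISSUE_SCALAR = 11.0
ADULT_RENAL_CL_L_H = 3.3


class HepaticClearanceParams(BaseModel):
    """Everything needed to scale cytosolic kinetics to the whole liver."""

    vmax_invitro: float  # nmol/min/mg cytosolic protein
    km: float  # mM
    tissue_scalar: float = LIVER_TISSUE_SCALAR
    cppgl: float = 80.7  # mg/g
    liver_mass: float  # g
    adh_fraction: float = 1.0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "HepaticClearanceParams":
        for name in ("vmax_invitro", "km", "tissue_scalar", "cppgl", "liver_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.adh_fraction <= 1:
            raise ValueError("adh_fraction must lie in [0, 1]")
        return self


class RenalClearanceParams(BaseModel):
    """Renal elimination: fixed clearance (adult) or GFR filtration (neonate)."""

    mode: Literal["fixed_adult", "gfr_neonate"]
    cl_fixed: float = ADULT_RENAL_CL_L_H  # L/h, adult mode
    gfr: float = 0.0  # mL/min, neonate mode
    fu_b: float = 0.825  # fraction unbound in blood

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "RenalClearanceParams":
        if self.mode == "fixed_adult" and self.cl_fixed <= 0:
            raise ValueError("cl_fixed must be positive in adult mode")
        if self.mode == "gfr_neonate" and self.gfr < 0:
            raise ValueError("gfr must be non-negative in neonate mode")
        return self


def whole_liver_vmax(p: HepaticClearanceParams, mw: float) -> float:
    """Whole-organ maximal metabolic rate in mg/h (see module docstring)."""
    nmol_per_min = (
        p.vmax_invitro * p.cppgl * p.liver_mass * p.tissue_scalar * p.adh_fraction
    )
    return nmol_per_min * 60.0 * mw * 1e-6


def hepatic_elimination_rate(
    c_liver: float,
    kp_liver: float,
    compound: CompoundParams,
    vmax_total: float,
    km_mass: float,
) -> float:
    """Saturable hepatic elimination rate (mg/h).

    ``c_liver`` is the liver tissue concentration (mg/L); ``kp_liver`` the
    (scaled) liver:plasma partition coefficient.  The unbound
    plasma-equivalent driver is Cu = fu_p * c_liver / kp_liver.
    """
    if c_liver < 0:
        c_liver = 0.0
    cu = compound.fu_plasma * c_liver / kp_liver
    return vmax_total * cu / (km_mass + cu)


def renal_elimination_rate(c_in: float, p: RenalClearanceParams) -> float:
    """Renal elimination rate (mg/h).

    Adult mode: rate = CL_R x plasma concentration entering the kidney.
    Neonate mode: rate = GFR (converted to L/h) x fu_B x blood
    concentration — pure glomerular filtration of unbound drug.
    """
    if c_in < 0:
        c_in = 0.0
    if p.mode == "fixed_adult":
        return p.cl_fixed * c_in
    return p.gfr * 60.0 / 1000.0 * p.fu_b * c_in


def hepatic_params_for(
    subject: Subject, vmax_invitro: float, km: float,
    tissue_scalar: float = LIVER_TISSUE_SCALAR,
) -> HepaticClearanceParams:
    """Per-subject hepatic scaling parameters."""
    return HepaticClearanceParams(
        vmax_invitro=vmax_invitro,
        km=km,
        tissue_scalar=tissue_scalar,
        cppgl=subject.cppgl,
        liver_mass=subject.liver_mass,
        adh_fraction=subject.adh_maturation,
    )


def renal_params_for(
    subject: Subject,
    compound: CompoundParams,
    cl_fixed: float = ADULT_RENAL_CL_L_H,
) -> RenalClearanceParams:
    """Per-subject renal parameters.

    Adults scale the fixed clearance by the sampled kidney-function
    multiplier and allometrically by body weight (exponent 0.75 around the
    81 kg reference); neonates use their sampled GFR.
    """
    fu_b = unbound_blood_fraction(compound)
    if subject.group == "adult":
        cl = cl_fixed * subject.renal_multiplier * (subject.weight / 81.0) ** 0.75
        return RenalClearanceParams(mode="fixed_adult", cl_fixed=cl, fu_b=fu_b)
    return RenalClearanceParams(mode="gfr_neonate", gfr=subject.gfr, fu_b=fu_b)


def km_mass_mg_l(km_mm: float, mw: float) -> float:
    """Michaelis constant converted to mass units (mg/L)."""
    return molar_to_mass_conc(km_mm, mw)


def well_stirred_hepatic_blood_cl(
    q_liver_blood: float, fu_b: float, clu_int: float
) -> float:
    """Closed-form well-stirred hepatic blood clearance.

    CL_h,b = Q_h * fu_B * CLu_int / (Q_h + fu_B * CLu_int) with CLu_int the
    intrinsic clearance referenced to unbound concentration (Vmax_total/Km
    in the first-order limit).  Used as an independent cross-check of the
    ODE model's low-dose hepatic extraction, never inside the ODE itself.
    """
    x = fu_b * clu_int
    return q_liver_blood * x / (q_liver_blood + x)
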