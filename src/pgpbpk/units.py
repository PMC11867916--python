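"""Compound constants and unit conversions.

Every module in this package works in one internal unit system — mg for
amounts, L for volumes, h for time, mg/L for concentrations.  The enzyme
kinetics literature reports the Michaelis constant of propylene glycol (PG)
in mM and the in-vitro maximum rate in nmol/min/mg cytosolic protein, so
all conversions between molar/enzymology units and the internal system live
here and happen exactly once, at module boundaries.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, model_validator

__all__ = [
    "CompoundParams",
    "UnitValue",
    "PG_DEFAULTS",
    "molar_to_mass_conc",
    "mass_to_molar_conc",
    "unbound_blood_fraction",
    "nmol_per_min_to_mg_per_h",
]


class CompoundParams(BaseModel):
    """Physicochemical and absorption constants of a single neutral solute.

    Defaults (see :data:`PG_DEFAULTS`) describe propylene glycol: a small,
    fully water-miscible diol (MW 76.06 g/mol, log P −0.92) that is almost
    entirely unbound in plasma and rapidly absorbed after oral dosing.
    """

    molecular_weight: float  # g/mol
    log_p: float  # log10 octanol:buffer partition coefficient
    fu_plasma: float  # fraction unbound in plasma, (0, 1]
    blood_to_plasma: float  # B:P concentration ratio
    compound_class: Literal["neutral", "acid", "base"] = "neutral"
    fa: float  # oral fraction absorbed, (0, 1]
    ka: float  # first-order absorption rate, 1/h

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "CompoundParams":
        if not self.molecular_weight > 0:
            raise ValueError("molecular_weight must be positive")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if not self.blood_to_plasma > 0:
            raise ValueError("blood_to_plasma must be positive")
        if not 0 < self.fa <= 1:
            raise ValueError("fa must be in (0, 1]")
        if not self.ka > 0:
            raise ValueError("ka must be positive")
        return self


#: Propylene glycol defaults.  The octanol:water log P of PG is −0.92 (PG is
#: miscible with water; a positive value would predict adipose-seeking
#: behaviour and a steady-state volume of distribution far above the
#: literature 0.80 L/kg).
PG_DEFAULTS = CompoundParams(
    molecular_weight=76.06,
    log_p=-0.92,
    fu_plasma=0.99,
    blood_to_plasma=1.2,
    compound_class="neutral",
    fa=0.99,
    ka=7.56,
)

_UNITS = ("mM", "mg/L", "nmol/min/mg", "mg/h", "L/h", "mL/min")


class UnitValue(BaseModel):
    """A magnitude tagged with one of the units this package exchanges."""

    magnitude: float
    unit: Literal["mM", "mg/L", "nmol/min/mg", "mg/h", "L/h", "mL/min"]

    model_config = {"frozen": True}

    def to(self, unit: str, mw: float | None = None) -> "UnitValue":
        """Convert to ``unit``; molar<->mass conversions need ``mw`` (g/mol)."""
        if unit not in _UNITS:
            raise ValueError(f"unknown unit {unit!r}")
        if unit == self.unit:
            return self
        pair = (self.unit, unit)
        if pair == ("mM", "mg/L"):
            return UnitValue(magnitude=molar_to_mass_conc(self.magnitude, _req(mw)), unit=unit)
        if pair == ("mg/L", "mM"):
            return UnitValue(magnitude=mass_to_molar_conc(self.magnitude, _req(mw)), unit=unit)
        if pair == ("mL/min", "L/h"):
            return UnitValue(magnitude=self.magnitude * 60.0 / 1000.0, unit=unit)
        if pair == ("L/h", "mL/min"):
            return UnitValue(magnitude=self.magnitude * 1000.0 / 60.0, unit=unit)
        raise ValueError(f"no conversion from {self.unit} to {unit}")


def _req(mw: float | None) -> float:
    if mw is None:
        raise ValueError("molecular weight required for molar<->mass conversion")
    return mw


def molar_to_mass_conc(c_mm: float, mw: float) -> float:
    """Convert a concentration in mM to mg/L.

    1 mM of a compound with molecular weight ``mw`` g/mol is ``mw`` mg/L.
    """
    if c_mm < 0:
        raise ValueError("concentration must be non-negative")
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return c_mm * mw


def mass_to_molar_conc(c_mg_l: float, mw: float) -> float:
    """Convert a concentration in mg/L to mM (inverse of molar_to_mass_conc)."""
    if c_mg_l < 0:
        raise ValueError("concentration must be non-negative")
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return c_mg_l / mw


def unbound_blood_fraction(p: CompoundParams) -> float:
    """Fraction unbound in whole blood, fu_B = fu_p / (B:P).

    Relates unbound plasma concentration to whole-blood concentration:
    Cu = fu_p * C_plasma = fu_B * C_blood.
    """
    return p.fu_plasma / p.blood_to_plasma


def nmol_per_min_to_mg_per_h(rate_nmol_min: float, mw: float) -> float:
    """Convert a molar rate (nmol/min) to a mass rate (mg/h)."""
    return rate_nmol_min * 60.0 * mw * 1e-6
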