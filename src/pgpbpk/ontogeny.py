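"""Maturation functions: ADH activity vs age and GFR vs body surface area.

Two developmental processes dominate propylene glycol elimination in early
life.  Hepatic alcohol dehydrogenase (ADH) activity rises from ~18% of the
adult level at birth along a sigmoid (Hill-type) maturation curve with
half-maximal age 0.9 years.  Renal function, expressed as glomerular
filtration rate (GFR), is described by a quadratic in body surface area
fitted to neonatal renal clearance data; the polynomial is a local fit and
goes negative below ~0.228 m², where it is clamped to zero (physiological
GFR cannot be negative).  A reference term neonate sits almost exactly at
that root, which is why sampled neonatal renal clearances are extremely
dispersed.
"""

from __future__ import annotations

from pydantic import BaseModel, model_validator

__all__ = [
    "AdhOntogenyParams",
    "GfrPolynomial",
    "ADH_ONTOGENY_DEFAULTS",
    "GFR_POLY_DEFAULTS",
    "adh_fraction",
    "gfr_from_bsa",
]


class AdhOntogenyParams(BaseModel):
    """Sigmoid-maturation parameters for fractional ADH activity."""

    f_birth: float = 0.18  # fraction of adult activity at birth
    f_max: float = 1.0  # asymptotic fraction
    age50: float = 0.9  # years to half-maximal maturation
    hill_n: float = 1.4  # Hill exponent

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "AdhOntogenyParams":
        if not 0 <= self.f_birth <= self.f_max:
            raise ValueError("need 0 <= f_birth <= f_max")
        if self.age50 <= 0:
            raise ValueError("age50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        return self


class GfrPolynomial(BaseModel):
    """GFR(BSA) = a0 + a1*BSA + a2*BSA^2, in mL/min, clamped at 0."""

    a0: float = -19.8  # mL/min
    a1: float = 89.04  # mL/min per m^2
    a2: float = -7.16  # mL/min per m^4

    model_config = {"frozen": True}


ADH_ONTOGENY_DEFAULTS = AdhOntogenyParams()
GFR_POLY_DEFAULTS = GfrPolynomial()


def adh_fraction(age: float, p: AdhOntogenyParams = ADH_ONTOGENY_DEFAULTS) -> float:
    """Fraction of adult ADH activity at ``age`` (years).

    f(age) = F_birth + (F_max - F_birth) * age^n / (Age50^n + age^n);
    strictly increasing, bounded in [F_birth, F_max).
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if age == 0:
        return p.f_birth
    a_n = age**p.hill_n
    return p.f_birth + (p.f_max - p.f_birth) * a_n / (p.age50**p.hill_n + a_n)


def gfr_from_bsa(bsa: float, poly: GfrPolynomial = GFR_POLY_DEFAULTS) -> float:
    """GFR in mL/min from body surface area in m², clamped at zero."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    raw = poly.a0 + poly.a1 * bsa + poly.a2 * bsa * bsa
    return max(0.0, raw)
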