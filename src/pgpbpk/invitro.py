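"""In-vitro ADH kinetics: NADH plate data -> Michaelis-Menten parameters.

The assay couples propylene glycol (PG) oxidation by cytosolic alcohol
dehydrogenase (ADH) to NADH formation (1:1 stoichiometry; the lactaldehyde/
ALDH pathway is blocked with disulfiram, so NADH production is attributed
entirely to ADH).  Absorbance at 340 nm is read at the start of incubation
and at 20 min; a NADH standard curve converts the absorbance change to nmol
NADH per well, hence to a rate per mg cytosolic protein.  The rate of NADH
formation equals the rate of PG disappearance.

Blank handling: the 0 mM substrate wells measure every NADH source that is
not PG oxidation; their mean rate is subtracted from all wells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from pydantic import BaseModel, model_validator

log = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "PlateAssay",
    "EnzymeKinetics",
    "MichaelisMentenFitError",
    "fit_standard_curve",
    "absorbance_to_rate",
    "fit_michaelis_menten",
    "michaelis_menten",
]

#: The plate design: 8 PG levels (mM), triplicate wells, 200 uL, 0.5 mg/mL
#: cytosolic protein, 20 min incubation, read at 340 nm.
ASSAY_CONCENTRATIONS_MM = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
ASSAY_PROTEIN_MG_ML = 0.5
ASSAY_WELL_VOLUME_UL = 200.0
ASSAY_INCUBATION_MIN = 20.0
ASSAY_REPLICATES = 3


class MichaelisMentenFitError(RuntimeError):
    """Raised when the nonlinear fit cannot converge; carries diagnostics."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear NADH standard curve: absorbance = slope * nmol + intercept."""

    slope: float  # absorbance per nmol NADH per well
    intercept: float  # absorbance
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("standard-curve slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


class PlateAssay(BaseModel):
    """One 96-well coupled-assay plate.

    ``substrate_conc`` lists the distinct PG levels (mM); the absorbance
    arrays have one row per level and one column per replicate.
    """

    substrate_conc: tuple[float, ...]
    absorbance_t0: tuple[tuple[float, ...], ...]
    absorbance_t20: tuple[tuple[float, ...], ...]
    replicates: int = ASSAY_REPLICATES
    protein_conc: float = ASSAY_PROTEIN_MG_ML  # mg/mL
    well_volume: float = ASSAY_WELL_VOLUME_UL  # uL
    incubation_time: float = ASSAY_INCUBATION_MIN  # min

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "PlateAssay":
        s = np.asarray(self.substrate_conc, dtype=float)
        if np.any(s < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if np.any(np.diff(np.unique(s)) <= 0) or len(np.unique(s)) != len(s):
            raise ValueError("substrate concentrations must be strictly increasing")
        if not np.all(np.diff(s) > 0):
            raise ValueError("substrate concentrations must be strictly increasing")
        if self.incubation_time <= 0:
            raise ValueError("incubation_time must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for arr in (self.absorbance_t0, self.absorbance_t20):
            if len(arr) != len(s) or any(len(row) != self.replicates for row in arr):
                raise ValueError("absorbance arrays must be n_conc x replicates")
        return self

    @property
    def protein_per_well_mg(self) -> float:
        return self.protein_conc * self.well_volume / 1000.0


class EnzymeKinetics(BaseModel):
    """Fitted Michaelis-Menten parameters with asymptotic 95% CIs.

    vmax in nmol/min/mg cytosolic protein; km in mM.
    """

    vmax: float
    km: float
    vmax_ci: tuple[float, float]
    km_ci: tuple[float, float]
    r_squared: float | None = None
    km_reliable: bool = True

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "EnzymeKinetics":
        if not self.vmax > 0 or not self.km > 0:
            raise ValueError("vmax and km must be positive")
        lo, hi = self.vmax_ci
        if not lo < self.vmax < hi:
            raise ValueError("vmax must lie inside its CI")
        lo, hi = self.km_ci
        if not lo < self.km < hi:
            raise ValueError("km must lie inside its CI")
        return self


#: Table-derived default kinetics of PG in pooled human liver cytosol.
PG_KINETICS = EnzymeKinetics(
    vmax=1.57, km=25.1, vmax_ci=(1.41, 1.74), km_ci=(15.7, 39.2)
)


def michaelis_menten(s, vmax: float, km: float):
    """v = Vmax * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_standard_curve(
    nadh_amounts: Sequence[float], absorbances: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares line through (nmol NADH, absorbance) points."""
    x = np.asarray(nadh_amounts, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.shape != y.shape:
        raise ValueError("nadh_amounts and absorbances must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct NADH levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in NADH amounts")
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def absorbance_to_rate(
    assay: PlateAssay, curve: StandardCurve
) -> list[tuple[float, float]]:
    """Convert per-well absorbance changes to blank-corrected mean rates.

    Returns ``(substrate mM, rate nmol/min/mg protein)`` for every nonzero
    substrate level.  The 0 mM wells (if present) define the blank rate,
    subtracted from all wells; negative blank-corrected rates are clipped to
    zero with a warning.
    """
    a0 = np.asarray(assay.absorbance_t0, dtype=float)
    a1 = np.asarray(assay.absorbance_t20, dtype=float)
    delta = a1 - a0
    # per-well nmol NADH formed; the curve intercept cancels in the delta
    nmol = delta / curve.slope
    rate = nmol / assay.incubation_time / assay.protein_per_well_mg
    s = np.asarray(assay.substrate_conc, dtype=float)
    if s[0] == 0.0:
        blank = float(np.mean(rate[0]))
        rate = rate - blank
        s_out, rate = s[1:], rate[1:]
    else:
        s_out = s
    mean_rates = rate.mean(axis=1)
    if np.any(mean_rates < 0):
        warnings.warn(
            "negative blank-corrected rates clipped to 0", stacklevel=2
        )
        log.warning("negative blank-corrected rates clipped to 0")
        mean_rates = np.clip(mean_rates, 0.0, None)
    return list(zip(s_out.tolist(), mean_rates.tolist()))


def fit_michaelis_menten(
    points: Sequence[tuple[float, float]], confidence: float = 0.95
) -> EnzymeKinetics:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Unweighted, with asymptotic confidence intervals from the fit covariance
    (t-distributed with n - 2 degrees of freedom).  A Km estimate outside
    (0, 10 x max S) is flagged unreliable via ``km_reliable=False``.
    """
    pts = [(float(s), float(v)) for s, v in points if s > 0]
    if len({s for s, _ in pts}) < 4:
        raise MichaelisMentenFitError(
            "need >= 4 distinct nonzero substrate levels"
        )
    s = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.all(v <= 0):
        raise MichaelisMentenFitError("all rates are non-positive")
    # initial guesses: Vmax from the plateau, Km from half-max crossing
    v0 = float(v.max()) * 1.1
    half = v0 / 2.2
    km0 = float(np.interp(half, np.sort(v), s[np.argsort(v)])) or float(np.median(s))
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten,
            s,
            v,
            p0=(v0, km0),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise MichaelisMentenFitError(f"Michaelis-Menten fit failed: {exc}") from exc
    vmax, km = (float(x) for x in popt)
    resid = v - michaelis_menten(s, vmax, km)
    dof = max(len(s) - 2, 1)
    ss_res = float(resid @ resid)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
    # widen degenerate (zero-width) intervals so the CI invariant holds for
    # noiseless data
    half_widths = np.maximum(tq * se, np.abs(popt) * 1e-12 + 1e-15)
    vmax_ci = (vmax - half_widths[0], vmax + half_widths[0])
    km_ci = (km - half_widths[1], km + half_widths[1])
    # a Km collapsed onto the lower boundary (fully saturated data) or far
    # beyond the design range cannot be estimated from this plate
    reliable = 1e-3 * float(s.min()) < km < 10.0 * float(s.max())
    if not reliable:
        log.warning("fitted Km %.3g outside (0, 10 x max S): flagged unreliable", km)
    return EnzymeKinetics(
        vmax=vmax,
        km=km,
        vmax_ci=(float(vmax_ci[0]), float(vmax_ci[1])),
        km_ci=(float(km_ci[0]), float(km_ci[1])),
        r_squared=r2,
        km_reliable=reliable,
    )
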