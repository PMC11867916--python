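"""Synthetic inputs: simulated assay plates and pseudo-clinical PK data.

The package needs no external datasets.  This module fabricates the two
kinds of raw input the analysis pipeline consumes, with the statistical
structure the validation workflow assumes:

* 96-well NADH absorbance plates for the in-vitro ADH assay — true
  Michaelis-Menten rates pushed through a known standard curve, with
  multiplicative lognormal well noise, at the fixed published design
  (8 PG levels 0-1000 mM in triplicate, 0.5 mg/mL cytosol, 200 µL,
  20 min, 340 nm);
* sparse clinical-style plasma concentration-time observations — per-subject
  PBPK simulations subsampled at a sparse schedule with multiplicative
  lognormal residual error, emulating opportunistic neonatal sampling.

It also hosts the model-qualification checks used on such observation
sets: the 2-fold criterion on AUC/CL and the visual-predictive-check (VPC)
band coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .engine import DoseRegimen, SolverConfig, simulate, subject_model
from .invitro import (
    ASSAY_CONCENTRATIONS_MM,
    ASSAY_INCUBATION_MIN,
    ASSAY_PROTEIN_MG_ML,
    ASSAY_REPLICATES,
    ASSAY_WELL_VOLUME_UL,
    EnzymeKinetics,
    PlateAssay,
    StandardCurve,
    michaelis_menten,
)
from .nca import auc_trapezoid, observed_clearance
from .population import PopulationSpec, Subject, generate_population

__all__ = [
    "ObservationSet",
    "DEFAULT_STANDARD_CURVE",
    "generate_plate",
    "generate_observations",
    "twofold_and_vpc",
    "ValidationReport",
]

#: A realistic NADH standard curve at 340 nm: ~6.22 mM^-1 cm^-1 extinction
#: over a ~0.55 cm path in a 200 µL well comes to ~0.017 absorbance per
#: nmol NADH per well, with a small instrument offset.
DEFAULT_STANDARD_CURVE = StandardCurve(slope=0.017, intercept=0.04, r_squared=1.0)

BLANK_RATE_NMOL_MIN_MG = 0.0  # disulfiram blocks the second NADH source


@dataclass(frozen=True)
class ObservationSet:
    """Sparse observed concentrations for a cohort under one regimen."""

    subject_id: np.ndarray  # int per observation
    times: np.ndarray  # h
    observed_conc: np.ndarray  # mg/L
    regimen: DoseRegimen
    group: Literal["adult", "term_neonate"]
    residual_cv: float
    doses_mg: np.ndarray  # per-subject dose per event, mg

    def for_subject(self, sid: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.subject_id == sid
        return self.times[m], self.observed_conc[m]

    @property
    def n_subjects(self) -> int:
        return int(self.subject_id.max()) + 1 if self.subject_id.size else 0


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


def generate_plate(
    kinetics: EnzymeKinetics,
    noise_cv: float = 0.0,
    seed: int = 0,
    curve: StandardCurve = DEFAULT_STANDARD_CURVE,
) -> PlateAssay:
    """Simulate one assay plate from known Michaelis-Menten parameters.

    Wells at 0 mM substrate carry only the blank signal; all wells share
    the instrument offset (the curve intercept) at t0 so that absorbance
    *changes* encode the NADH formed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    s = np.asarray(ASSAY_CONCENTRATIONS_MM)
    protein_mg = ASSAY_PROTEIN_MG_ML * ASSAY_WELL_VOLUME_UL / 1000.0
    rates = michaelis_menten(s, kinetics.vmax, kinetics.km) + BLANK_RATE_NMOL_MIN_MG
    nmol = rates * ASSAY_INCUBATION_MIN * protein_mg  # per well over 20 min
    nmol_wells = nmol[:, None] * _lognormal_noise(
        rng, noise_cv, (s.size, ASSAY_REPLICATES)
    )
    a0 = np.full((s.size, ASSAY_REPLICATES), curve.intercept)
    a20 = a0 + nmol_wells * curve.slope
    return PlateAssay(
        substrate_conc=tuple(s.tolist()),
        absorbance_t0=tuple(map(tuple, a0.tolist())),
        absorbance_t20=tuple(map(tuple, a20.tolist())),
    )


DEFAULT_SPARSE_SAMPLES = 6


def generate_observations(
    spec: PopulationSpec,
    regimen: DoseRegimen,
    n_subjects: int | None = None,
    sparse_schedule: Sequence[float] | None = None,
    residual_cv: float = 0.2,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
) -> ObservationSet:
    """Simulate a cohort and subsample noisy observations.

    ``sparse_schedule`` lists sampling times (h) relative to the start of
    the final dosing interval; the default is 6 samples spread over that
    interval.  Residual error is multiplicative lognormal.
    """
    if n_subjects is not None:
        spec = spec.model_copy(update={"n_subjects": n_subjects})
    rng = np.random.default_rng(seed)
    tau = regimen.interval
    t0 = (regimen.n_doses - 1) * tau
    if sparse_schedule is None:
        sparse_schedule = np.linspace(0.5, tau, DEFAULT_SPARSE_SAMPLES)
    sched = np.asarray(sparse_schedule, dtype=float)
    duration = regimen.n_doses * tau
    if np.any(t0 + sched > duration + 1e-9):
        raise ValueError("sparse schedule extends beyond the simulation horizon")
    subjects = generate_population(spec)
    sid, times, concs, doses = [], [], [], []
    for i, subject in enumerate(subjects):
        res = simulate(subject_model(subject), regimen, duration, solver_cfg)
        c = np.interp(t0 + sched, res.times, res.plasma_conc)
        c = c * _lognormal_noise(rng, residual_cv, c.size)
        sid.extend([i] * sched.size)
        times.extend((t0 + sched).tolist())
        concs.extend(c.tolist())
        doses.append(regimen.dose_per_event * subject.weight)
    return ObservationSet(
        subject_id=np.asarray(sid),
        times=np.asarray(times),
        observed_conc=np.asarray(concs),
        regimen=regimen,
        group=spec.group,
        residual_cv=residual_cv,
        doses_mg=np.asarray(doses),
    )


@dataclass(frozen=True)
class ValidationReport:
    """2-fold and VPC summaries for one observation set."""

    frac_auc_within_2fold: float
    frac_cl_within_2fold: float
    frac_points_in_band: float
    pass_2fold: bool
    pass_vpc: bool
    n_subjects: int


def twofold_and_vpc(
    pred_population: Sequence[Subject],
    obs: ObservationSet,
    threshold: float = 0.90,
    solver_cfg: SolverConfig | None = None,
) -> ValidationReport:
    """Model-qualification check against an observation set.

    Predicted AUC/CL are computed from the prediction population's
    geometric-mean profile over the observation interval; observed
    AUC/CL per subject come from trapezoidal integration of that
    subject's sparse samples.  The VPC band is the pointwise 5th-95th
    percentile of the predicted individual profiles at the observation
    times.  Pass flags use the ~90% convention.
    """
    if obs.subject_id.size == 0:
        raise ValueError("empty observation set")
    if pred_population[0].group != obs.group:
        raise ValueError(
            f"population group {pred_population[0].group!r} does not match "
            f"observations {obs.group!r}"
        )
    regimen = obs.regimen
    tau = regimen.interval
    t_end = regimen.n_doses * tau
    t0 = t_end - tau
    profiles = []
    for subject in pred_population:
        res = simulate(subject_model(subject), regimen, t_end, solver_cfg)
        profiles.append((res.times, res.plasma_conc, subject.weight))

    # predicted interval AUC per prediction subject -> geometric means
    pred_aucs = np.array(
        [auc_trapezoid(t, c, t0, t_end) for t, c, _ in profiles]
    )
    pred_cls = np.array(
        [
            observed_clearance(regimen.dose_per_event * w, a)
            for (_, _, w), a in zip(profiles, pred_aucs)
        ]
    )
    gm_auc = float(np.exp(np.mean(np.log(pred_aucs))))
    gm_cl = float(np.exp(np.mean(np.log(pred_cls))))

    n = obs.n_subjects
    ok_auc = ok_cl = 0
    for i in range(n):
        t, c = obs.for_subject(i)
        if t.size < 2 or np.all(c <= 0):
            continue
        auc_i = float(np.trapezoid(c, t)) * tau / (t[-1] - t[0])
        cl_i = obs.doses_mg[i] / max(auc_i, 1e-300)
        if 0.5 <= auc_i / gm_auc <= 2.0:
            ok_auc += 1
        if 0.5 <= cl_i / gm_cl <= 2.0:
            ok_cl += 1

    # VPC: pointwise 5th-95th percentile band of predicted profiles
    obs_t = np.unique(obs.times)
    band = np.array(
        [np.interp(obs_t, t, c) for t, c, _ in profiles]
    )
    lo = np.percentile(band, 5, axis=0)
    hi = np.percentile(band, 95, axis=0)
    lo_at = np.interp(obs.times, obs_t, lo)
    hi_at = np.interp(obs.times, obs_t, hi)
    tol = 1e-9 * np.maximum(hi_at, 1.0)
    inside = (obs.observed_conc >= lo_at - tol) & (obs.observed_conc <= hi_at + tol)
    frac_in = float(np.mean(inside))

    frac_auc = ok_auc / n
    frac_cl = ok_cl / n
    return ValidationReport(
        frac_auc_within_2fold=frac_auc,
        frac_cl_within_2fold=frac_cl,
        frac_points_in_band=frac_in,
        pass_2fold=bool(min(frac_auc, frac_cl) >= threshold),
        pass_vpc=bool(frac_in >= threshold),
        n_subjects=n,
    )
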